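# Methods

## The removal model for chemical eradication

The package models a monthly removal programme at a site with `P`
monitoring points surveyed over `T` months. In month `t` each living
individual at point `i` first survives or dies from the pesticide
application (per-capita probability `d_{t,i}`), then, if alive, is caught
on a sticky trap or evades it (probability `c_{t,i}`). Both removals are
permanent; the population is closed otherwise (no births, deaths from
other causes, or movement between points). The within-month ordering —
death strictly before capture — is the package's single canonical
convention; it matches the interpretation that an ant contacting bait dies
within the three-day trapping window and can no longer be caught.

Writing `phi_{t,i} = prod_{k<=t}(1-d_{k,i})(1-c_{k,i})` (with
`phi_0 = 1`) for the joint probability of escaping every removal through
month `t`, the joint probability of a *first removal by capture* in month
`t` is `pi'_{t,i} = phi_{t-1,i}(1-d_{t,i})c_{t,i}`, and by death
`delta_{t,i} = phi_{t-1,i} d_{t,i}`. These partition an individual's fate:
`sum_t pi' + sum_t delta + phi_T = 1` exactly, which the code verifies to
1e-12 per point (all joint products are accumulated in log space, so
59-month horizons cannot underflow).

The observation layer is the standard removal-protocol mixture: conditional
on the total `n_i` of individuals ever captured at point `i`, the monthly
counts `y_{t,i}` are multinomial with cell probabilities
`pi'_{t,i} / sum_k pi'_{k,i}`; `n_i` is a binomial thinning of the latent
initial abundance `N_i` with success probability
`q_i = sum_k pi'_{k,i}`; and `N_i` is negative binomial with mean `mu` and
size `sigma` (variance `mu + mu^2/sigma`), accommodating the strong
point-to-point abundance heterogeneity of ant infestations.

Covariate corrections: `c_{t,i} = c'_t · hold_{t,i}` zeroes detection at a
lost trap (the bait can still kill that month — the correction touches
detection only), and `d_{t,i} = d' · chem_{t,i}` zeroes pesticide death in
months without bait application. Detection is survey-constant by default;
a complementary log-log temperature link
`c'_t = 1 - exp(-exp(b0 + b1·Temperature_t))` is available but off by
default, reflecting that ant activity plausibly rises with temperature yet
the effect is typically too weak to matter over a multi-year programme.

## Marginal likelihood

The negative binomial family is closed under binomial thinning: if
`N ~ NegBin(mu, sigma)` (success probability `p = sigma/(sigma+mu)`) and
`n | N ~ Binomial(q, N)`, then `n ~ NegBin` with the same size and success
probability `p' = p / (p + q(1-p))`. The likelihood therefore factorises
per point into a multinomial term and this thinned marginal, with every
`N_i` integrated out analytically. The tests verify the closed form
against explicit truncated summation over `N` (tail mass < 1e-12) to 1e-8
on randomized small instances.

Impossible data — a positive count where the cell probability is zero, or
`n_i > 0` where the total capture probability is zero — return `-inf`
rather than raising, so the sampler can simply reject such parameter
values. File readers additionally reject counts at lost-trap months with a
row-level error.

The conditional of the latent abundance is likewise closed-form:
`N_i - n_i ~ NegBin(n_i + sigma, p + q_i - p·q_i)`, so `N_i >= n_i` holds
by construction and exact conditional draws are cheap.

## Priors, sampler, diagnostics

Priors follow near-non-informative programme practice: uniform(0,1) on
`c'` and `d'` (vague normal(0, 10) on `b0`, `b1` when the temperature link
is used) and gamma(0.01, 0.01) on `mu` and `sigma`. The gamma
hyperparameters are configurable; nothing in the package's conclusions is
sensitive to them at these settings.

Sampling is adaptive Metropolis-within-Gibbs on transformed parameters
(logit for probabilities, log for `mu`, `sigma`): one random-walk update
per parameter per iteration, proposal scales adapted every 100 burn-in
iterations toward ~30% acceptance and frozen afterwards. Because the
marginal likelihood is nearly flat along the ridge
`(1-c')(1-d') = const` whenever bait was applied in almost every surveyed
month (see below), the sampler adds one correlated move per iteration that
perturbs `d'` while holding the joint survival factor and the expected
capture total fixed (log-`mu` is shifted by the capture-total ratio), with
the appropriate Jacobian correction. This move leaves the posterior
untouched and cuts the split R-hat on `c'` and `d'` from ~1.06 to ~1.00 at
desk-scale iteration counts.

Chains start from overdispersed, data-informed points (detection uniform
on (0.05, 0.95), death log-uniform on (1e-4, 0.5), `mu` a random multiple
of the mean removal count, `sigma` log-uniform on (0.3, 10)), re-drawn
until the posterior is finite. Raw draws from the gamma(0.01, 0.01) prior
would routinely start chains at `mu ~ 1e-30`, which a short burn-in cannot
recover from; the data-informed cloud is deliberately much wider than any
posterior encountered in testing, so the multi-chain R-hat check retains
its force. Convergence uses the rank-normalized split R-hat (via `arviz`),
requiring at least two chains.

Default settings retain 2,200 draws per chain from 22,000 post-burn-in
iterations (burn-in 2,000, thinning 10, three chains) — a desk-scale
choice that keeps a programme-scale fit around half a minute;
`MCMCConfig.programme_scale()` provides the 220,000/20,000/100 configuration
for production runs. Latent `N_i` are drawn exactly at every retained
iteration.

## Identifiability: what the data can and cannot pin down

With survey-constant probabilities and bait on in effectively every
surveyed month, the multinomial cells depend on `(c', d')` only through
the product `(1-c')(1-d')`, and the thinning closure lets `mu` absorb any
change in the capture total with `sigma` unchanged — so `c'` and `d'` are
*jointly unidentified* along that ridge. Separation comes only from months
in which bait was off while ants were plausibly present: in the programme
this means chiefly the plot whose pesticide applications started eleven
months late, plus months where the plot-level six-month rule had switched
bait off, plus (weakly) lost-trap months.

Two design consequences. First, multi-site data should be fitted jointly
(`fit --pool`, `io.combine_sites`): the probabilities are programme-wide,
so a site without its own bait-off exposure borrows identification from
one that has it; fitted alone, such a site's death probability drifts
upward along the ridge and its abundance total inflates by tens of
percent. Second, even in the pooled fit the death probability remains
weakly identified — its posterior spans roughly two orders of magnitude —
and the residual ridge mass biases the posterior mean of `c'` slightly
below the generating value (about 0.01 at programme scale) and the
abundance total slightly above (under ten percent). The recovery tests
quantify both on synthetic data; a real programme wanting a sharp `d'`
estimate needs deliberately scheduled bait-off monitoring months.

## Eradication probability and declaration

For each retained posterior draw, survivor counts are drawn as
`s_{t,i} ~ Binomial(N_i, phi_{t,i})` — a marginal construction, redrawn
independently per month, so survivor paths are not forced monotone within
a draw. The site-level presence probability is
`Ps_t = Pr(sum_i s_{t,i} >= 1)`, the posterior probability that at least
one ant is still alive in month `t` (note the direction: declaration
happens when the *presence* probability falls, and stays, below 0.05 or
0.01). The declaration month uses a sustained-crossing rule — the first
month after which every later month is also below threshold — so isolated
Monte-Carlo blips cannot trigger an early declaration; a threshold never
sustainedly crossed yields an explicit "not yet eradicated" result rather
than an error.

## Net expected cost and optimal stopping

Declaring eradication after `m` consecutive detection-free months costs

    NEC(m) = (m - 1) · Cs + presence(m) · Ce

where `Cs` is the monthly monitoring cost, `Ce` the cost of escape and
damage if ants persist after the declaration, and `presence(m)` is read
from the `Ps` series at calendar month `last_detection + m` (so `m = 1` is
the first monitoring month after the last sighting — the cheapest possible
declaration incurs no further monitoring cost). An optional surcharge
vector adds continued-pesticide costs for the first months after the last
sighting (off by default; like `Cs`, month `k`'s surcharge accrues only if
monitoring continues past it). The optimal month minimises the curve;
exact ties break toward the earlier month, which is cheaper under any
unmodelled discounting. For a non-increasing presence series the optimal
month is non-decreasing in `Ce/Cs`; the sensitivity table scans a ratio
grid (default use case 25-200). Costs are plain decimal quantities with
whatever currency the configuration uses.

## The simulator

`simulate.simulate_site` is an individual-based generator of the whole
programme, used by every downstream test: `N_i ~ NegBin(mu, sigma)` per
point, death-then-capture removals at the true `c'`, `d'`, Bernoulli trap
loss (default 0.02/month), and bait applications driven by the plot-level
six-month rule — bait on while any point of the plot had a detection in
the previous six months, with pre-programme months counting as detections
(a sighting is what triggers a programme), and per-plot start months to
represent delayed plots. Points are grouped into plots of three by
default, matching ~1-ha treatment plots holding a few monitoring points
each. Simulation is at the individual level so the truth record carries
every ant's fate month and cause; the induced counts are distributionally
identical to aggregated binomial thinning, and a chi-square test confirms
the simulator and the likelihood describe the same process.

The two presets mirror the programme's shape: 23 points with total
abundance calibrated to ~1400 (rejection-sampling the NegBin abundance
vector to within 5% of the target, preserving its shape) and 28 points
calibrated to ~4200 with one full plot's pesticide delayed to month 12,
both over 59 monthly surveys, optionally with the first survey's traps
lost.

What the simulator does *not* emulate — and hence what passing recovery
tests do not certify about real data: worker turnover (queens replenishing
the population during the programme), movement or budding between points,
visual-observation detections feeding the bait rule, seasonal activity
cycles, and any deviation from the model's closed-population assumption.
On real data these features would chiefly manifest as extra bait-off/on
cycling and longer detection tails, i.e. *more* information about `d'`
than the synthetic scenarios contain.

## Numerical and interface conventions

- Joint probabilities in log space; conservation checked after
  exponentiation (1e-12); `-inf` log likelihood (never an exception) for
  impossible data during sampling.
- Month indices are 1-based everywhere a user sees them; survey tables are
  long-format UTF-8 CSV with required columns
  `site, point_id, month_index, count, hold, chem`, unique keys, and
  gapless months per site after an optional exclusion list (excluded
  months — e.g. a first survey whose traps were lost — are dropped and the
  remaining months re-based).
- All randomness flows from a single integer seed per command; posterior
  draws serialise to CSV (one row per retained draw) with a JSON sidecar
  carrying the package version, configuration, R-hat values and SHA-256
  input hashes.
- Test-suite problem sizes are deliberate desk-scale reductions (22,000
  iterations, 12-replicate coverage studies at 30 points x 40 surveys);
  programme-scale settings remain available through the configuration
  objects.

## Known limitations

- `d'` is weakly identified by design-typical data (see above); its
  posterior is honest but wide, and summaries of `c'` and abundance
  inherit a small ridge-induced bias quantified in the recovery tests.
- The closed-population assumption makes the model unsuitable while a
  colony is still reproducing strongly; it is intended for the collapse
  phase of an eradication programme.
- `Ps_t` is pooled per site; per-point presence probabilities are
  available from the survivor draws but no spatial risk model is included.
- No discounting or budget allocation in the cost model; `Ce` is a single
  scenario value, explored only through the ratio grid.
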