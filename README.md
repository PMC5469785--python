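# eradimix

Bayesian removal-sampling toolkit for deciding **when an invasive-ant
eradication programme can declare success**.

Monitoring programmes against the Argentine ant (*Linepithema humile*) treat
infested sites with toxic bait month after month while sticky traps track the
collapsing worker population. Once captures stop, managers face the classic
absence problem: zero detections do not mean zero ants. `eradimix`
implements a multinomial-mixture removal model for *chemical* eradication —
individuals leave the population either by being caught in a trap or by being
killed by the pesticide — and turns monthly trap counts plus the
bait-application history into:

- posterior estimates of the per-capita monthly detection probability `c'`,
  the per-capita pesticide death probability `d'`, and the latent initial
  abundance `N_i` at every monitoring point;
- the posterior probability `Ps_t` that at least one ant is still alive in
  month `t`, with 95%/99% declaration months (the first month after which
  `Ps_t` stays below 0.05 / 0.01);
- the net expected cost `NEC(m) = (m−1)·Cs + presence(m)·Ce` of declaring
  eradication after `m` detection-free months, its minimiser (the optimal
  stopping month), and a cost-ratio sensitivity table.

## Model

For point `i` and survey `t`, with death acting before capture within a
month,

```
phi_{t,i} = prod_{k<=t} (1 - d_{k,i}) (1 - c_{k,i})        # never removed through t
pi'_{t,i} = phi_{t-1,i} (1 - d_{t,i}) c_{t,i}              # first removal BY CAPTURE at t
y_{.,i} ~ Multinomial(pi'_{.,i} / sum_k pi'_{k,i}, n_i)
n_i     ~ Binomial(sum_k pi'_{k,i}, N_i)
N_i     ~ NegBin(mu, sigma)        # variance mu + mu^2/sigma
s_{t,i} ~ Binomial(N_i, phi_{t,i})  # posterior survivors
```

with `c_{t,i} = c' · hold_{t,i}` (lost traps detect nothing) and
`d_{t,i} = d' · chem_{t,i}` (no bait, no pesticide death). An optional
complementary log-log link `c'_t = 1 − exp(−exp(b0 + b1·Temperature_t))`
makes detection temperature-dependent. Setting `d' ≡ 0` recovers the
classic capture-only removal model. Because the negative binomial family is
closed under binomial thinning, the latent `N_i` are integrated out of the
likelihood in closed form; the sampler (adaptive Metropolis-within-Gibbs
with an extra ridge-aligned move) only explores `(c', d', mu, sigma)` and
draws each `N_i` exactly from its conditional. See `docs/methods.md` for
the details and the identifiability discussion.

## Worked example

The study's raw trap data are not public, so the package ships an
individual-based simulator of the whole programme (negative-binomial point
abundances, death-then-capture removals, Bernoulli trap loss, and the
six-month plot-level bait rule, including one plot whose pesticide starts
eleven months late). The `programme` preset writes both sites — 23 points
calibrated to ~1400 ants and 28 points calibrated to ~4200 — into one file;
they are then fitted jointly, exactly because the death probability is only
identified by months in which bait was off while ants were present:

```bash
eradimix simulate --preset programme --seed 1 --out-data programme.csv
eradimix fit programme.csv --pool --seed 2 --out posterior
eradimix eradicate posterior programme.csv --site tokai --seed 3 \
    --out-ps ps_tokai.csv --out-summary declaration_tokai.json
eradimix nec ps_tokai.csv --cs 40000 --ce-ratio 59.8 --ratios 25,50,100,200 \
    --out-curve nec.csv --out-summary nec.json
```

which prints (generating values `c' = 0.279`, `d' = 0.00539`):

```
simulated site 'tokai': 23 points x 59 surveys, 1340 captures, true N total 1372
simulated site 'jonan': 28 points x 59 surveys, 3953 captures, true N total 4025
fitting 'jonan+tokai': 51 points x 59 surveys, 5293 captures
c      mean 0.2615  95% CI [0.2334, 0.2808]  R-hat 1.000
d      mean 0.02346  95% CI [0.001241, 0.05731]  R-hat 1.000
mu     mean 113.4  95% CI [78.23, 161.7]  R-hat 1.000
sigma  mean 0.5833  95% CI [0.4042, 0.8054]  R-hat 1.000
t95=33 t99=39 (last detection month 25)
optimal stopping m=6 (calendar month 31), NEC 373239
```

Reading this: the detection probability is recovered near its generating
value with a converged sampler; the death probability is, as expected, only
weakly identified (its 95% interval spans more than an order of magnitude,
mirroring the programme's own experience). Ants were last caught at this
site in month 25; the presence probability falls below 5% for good in month
33 and below 1% in month 39, so a 99% declaration waits 14 months after the
last sighting. With monitoring at 40,000 per month and an escape cost of
59.8 monthly costs, the expected-cost minimum arrives at calendar month 31
— six detection-free months, slightly *before* the 95% declaration month —
and costs 373,239, illustrating the usual trade-off: stopping at the
cost-optimal month accepts a measurably higher escape risk than the 99%
criterion.

`fit --no-chemical-term` runs the capture-only variant; every command takes
`--seed`, and rerunning with the same inputs and seed reproduces every
artifact.

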