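"""Bayesian estimation of the removal model by Metropolis-within-Gibbs MCMC.

The latent initial abundances ``N_i`` are integrated out of the likelihood
analytically (negative-binomial thinning; see :mod:`eradimix.model_core`), so
the sampler only has to explore the low-dimensional parameter block
``(c' or beta0/beta1, d', mu, sigma)``.  Each parameter is updated by a
random-walk Metropolis step on a transformed scale (logit for probabilities,
log for ``mu`` and ``sigma``), with proposal scales adapted during burn-in
towards a 20-45% acceptance rate and frozen afterwards.  At every retained
iteration the latent ``N_i`` are drawn exactly from their conditional
``N_i - n_i ~ NegBin(n_i + sigma, p + q_i - p q_i)``.

Priors follow the programme's near-non-informative choices: uniform(0,1) on
the detection and death probabilities (vague normals on the cloglog
coefficients when the temperature covariate is used) and gamma distributions
on ``mu`` and ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, xlogy

from .model_core import (
    CountData,
    ModelParams,
    SurveyDesign,
    detection_link,
    marginal_loglik,
)

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "fit",
    "sample_latent_N",
    "rhat",
    "summarize",
]


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    Probabilities get uniform(0,1) priors; ``mu`` and ``sigma`` get
    gamma(shape, rate) priors, near-non-informative by default; the cloglog
    coefficients get independent normal(0, beta_scale) priors.
    """

    mu_shape: float = 0.01
    mu_rate: float = 0.01
    sigma_shape: float = 0.01
    sigma_rate: float = 0.01
    beta_scale: float = 10.0

    def __post_init__(self) -> None:
        for name in ("mu_shape", "mu_rate", "sigma_shape", "sigma_rate", "beta_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``n_iter`` counts post-burn-in iterations; ``n_iter // thin`` draws are
    retained per chain.  The defaults are a desk-scale reduction of the
    programme-scale settings available via :meth:`programme_scale`
    (220,000 iterations after a 20,000-iteration burn-in, thinning 100,
    three chains).
    """

    n_iter: int = 22_000
    n_burnin: int = 2_000
    thin: int = 10
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.n_burnin < 0:
            raise ValueError("need n_iter > 0 and n_burnin >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @classmethod
    def programme_scale(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_iter=220_000, n_burnin=20_000, thin=100, n_chains=3, seed=seed)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, kept per chain for diagnostics.

    ``params`` has shape ``(n_chains, n_draws, k)`` in the order of
    ``param_names``; ``N`` has shape ``(n_chains, n_draws, P)``.
    """

    param_names: list[str]
    params: np.ndarray
    N: np.ndarray
    config: MCMCConfig
    rng_seed: int
    acceptance: Optional[np.ndarray] = None  # (n_chains, k) post-burn-in rates

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[1]

    @property
    def n_points(self) -> int:
        return self.N.shape[2]

    def flat(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        j = self.param_names.index(name)
        return self.params[:, :, j].reshape(-1)

    def flat_params(self) -> np.ndarray:
        return self.params.reshape(-1, self.params.shape[2])

    def flat_N(self) -> np.ndarray:
        return self.N.reshape(-1, self.N.shape[2])

    def subset_points(self, sl: slice) -> "PosteriorDraws":
        """Same parameter draws, latent abundances restricted to a slice of
        points (e.g. one site of a pooled multi-site fit)."""
        return PosteriorDraws(
            param_names=self.param_names,
            params=self.params,
            N=self.N[:, :, sl],
            config=self.config,
            rng_seed=self.rng_seed,
            acceptance=self.acceptance,
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw: chain, draw, parameters, N_1..N_P."""
        rows = {
            "chain": np.repeat(np.arange(self.n_chains), self.n_draws),
            "draw": np.tile(np.arange(self.n_draws), self.n_chains),
        }
        flat = self.flat_params()
        for j, name in enumerate(self.param_names):
            rows[name] = flat[:, j]
        flatN = self.flat_N()
        for i in range(self.n_points):
            rows[f"N_{i + 1}"] = flatN[:, i]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, config: MCMCConfig, rng_seed: int = 0
    ) -> "PosteriorDraws":
        n_cols = sorted(
            (c for c in frame.columns if c.startswith("N_")),
            key=lambda c: int(c[2:]),
        )
        param_names = [c for c in frame.columns if c not in ("chain", "draw") and not c.startswith("N_")]
        chains = np.sort(frame["chain"].unique())
        per = [frame[frame["chain"] == ch].sort_values("draw") for ch in chains]
        n_draws = min(len(p) for p in per)
        params = np.stack([p[param_names].to_numpy()[:n_draws] for p in per])
        N = np.stack([p[n_cols].to_numpy(dtype=np.int64)[:n_draws] for p in per])
        return cls(param_names=list(param_names), params=params, N=N, config=config, rng_seed=rng_seed)


def sample_latent_N(n_i, capture_total, mu: float, sigma: float, rng, size=None):
    """Exact draw from ``Pr(N | n)`` under the thinned negative binomial.

    The conditional of the unseen remainder is
    ``N - n ~ NegBin(size n + sigma, prob p + q - pq)`` with
    ``p = sigma / (sigma + mu)`` and ``q`` the total capture probability, so
    ``N >= n`` always.  ``capture_total = 1`` forces ``N = n`` exactly.
    """
    n = np.asarray(n_i)
    q = np.asarray(capture_total, dtype=float)
    if (n < 0).any():
        raise ValueError("n_i must be nonnegative")
    if ((q <= 0) & (n > 0)).any():
        raise ValueError("capture_total must be positive wherever n_i > 0")
    if ((q < 0) | (q > 1)).any():
        raise ValueError("capture_total must lie in (0, 1]")
    p = sigma / (sigma + mu)
    a = p + q * (1.0 - p)
    extra = rng.negative_binomial(n + sigma, a, size=size)
    out = n + extra
    if np.ndim(n_i) == 0 and size is None:
        return int(out)
    return out


class _ConstantLoglik:
    """Fast repeated evaluation of the marginal log likelihood.

    For survey-constant ``c'`` and ``d'`` the log cell probability at a held
    trap reduces to an affine function of ``log c'``, ``log(1-c')`` and
    ``log(1-d')`` with integer coefficients fixed by the design, so the
    per-evaluation cost is one ``exp`` over the ``(T, P)`` grid.
    """

    def __init__(self, data: CountData, design: SurveyDesign, chemical_term: bool = True):
        data.check_consistent(design)
        hold = design.hold.astype(float)
        chem = design.chem.astype(float)
        self.chemical_term = chemical_term
        self.chem_inc = np.cumsum(chem, axis=0)  # bait applications through t
        self.hold_exc = np.cumsum(hold, axis=0) - hold  # held surveys before t
        self.hold = hold
        y = data.y
        self.n = data.n.astype(float)
        self.S_y = float(y.sum())
        self.S_hold = float((y * self.hold_exc).sum())
        self.S_chem = float((y * self.chem_inc).sum())
        self.lgamma_const = float(gammaln(data.n + 1).sum() - gammaln(y + 1).sum())
        self.P = design.n_points

    def capture_total(self, c: float, d: float) -> np.ndarray:
        a = np.log1p(-c)
        M = self.hold_exc * a
        if self.chemical_term and d > 0.0:
            M = M + self.chem_inc * np.log1p(-d)
        return c * (np.exp(M) * self.hold).sum(axis=0)

    def __call__(self, c: float, d: float, mu: float, sigma: float) -> float:
        if not (0.0 < c < 1.0 and 0.0 <= d < 1.0 and mu > 0.0 and sigma > 0.0):
            return float("-inf")
        q = self.capture_total(c, d)
        if ((q <= 0.0) & (self.n > 0)).any():
            return float("-inf")
        b = np.log1p(-d) if (self.chemical_term and d > 0.0) else 0.0
        mult = (
            self.S_y * np.log(c)
            + self.S_hold * np.log1p(-c)
            + self.S_chem * b
            - xlogy(self.n, q).sum()
            + self.lgamma_const
        )
        r = sigma
        p = r / (r + mu)
        a = p + q * (1.0 - p)
        p_thin = p / a
        marg = (
            gammaln(self.n + r).sum()
            - self.P * gammaln(r)
            + r * np.log(p_thin).sum()
            + xlogy(self.n, 1.0 - p_thin).sum()
            - gammaln(self.n + 1).sum()
        )
        return float(mult + marg)


class _TemperatureLoglik:
    """Marginal log likelihood with the cloglog temperature link (slow path)."""

    def __init__(self, data: CountData, design: SurveyDesign, chemical_term: bool = True):
        data.check_consistent(design)
        if design.temperature is None:
            raise ValueError("temperature covariate requested but the design has none")
        self.data = data
        self.design = design
        self.chemical_term = chemical_term
        self.n = data.n.astype(float)

    def __call__(self, beta0: float, beta1: float, d: float, mu: float, sigma: float) -> float:
        params = ModelParams(
            c_const=0.5,
            d_const=d,
            mu=mu,
            sigma=sigma,
            beta0=beta0,
            beta1=beta1,
            use_temperature=True,
            chemical_term=self.chemical_term,
        )
        return marginal_loglik(params, self.design, self.data, strict=False)

    def capture_total(self, beta0: float, beta1: float, d: float) -> np.ndarray:
        from .model_core import effective_probs, removal_probabilities

        params = ModelParams(
            c_const=0.5,
            d_const=d,
            mu=1.0,
            sigma=1.0,
            beta0=beta0,
            beta1=beta1,
            use_temperature=True,
            chemical_term=self.chemical_term,
        )
        c, dd = effective_probs(params, self.design)
        return removal_probabilities(c, dd).capture_total


def _run_chain(
    loglik,
    names: list[str],
    priors: PriorSpec,
    config: MCMCConfig,
    data: CountData,
    use_temperature: bool,
    chemical_term: bool,
    seed_seq: np.random.SeedSequence,
):
    rng = np.random.default_rng(seed_seq)
    k = len(names)
    n_keep = config.n_iter // config.thin
    P = data.n.shape[0]

    def natural(theta):
        vals = {}
        j = 0
        if use_temperature:
            vals["beta0"], vals["beta1"] = theta[0], theta[1]
            j = 2
        else:
            vals["c"] = expit(theta[0])
            j = 1
        if chemical_term:
            vals["d"] = expit(theta[j])
            j += 1
        vals["mu"] = np.exp(theta[j])
        vals["sigma"] = np.exp(theta[j + 1])
        return vals

    def log_posterior(theta):
        v = natural(theta)
        lp = 0.0
        if use_temperature:
            lp += -0.5 * (v["beta0"] / priors.beta_scale) ** 2
            lp += -0.5 * (v["beta1"] / priors.beta_scale) ** 2
            args = (v["beta0"], v["beta1"])
        else:
            # uniform(0,1) prior + logit Jacobian
            lp += np.log(v["c"]) + np.log1p(-v["c"])
            args = (v["c"],)
        d = 0.0
        if chemical_term:
            lp += np.log(v["d"]) + np.log1p(-v["d"])
            d = v["d"]
        # gamma prior + log Jacobian: a*log(x) - b*x (up to constants)
        lp += priors.mu_shape * np.log(v["mu"]) - priors.mu_rate * v["mu"]
        lp += priors.sigma_shape * np.log(v["sigma"]) - priors.sigma_rate * v["sigma"]
        if not np.isfinite(lp):
            return float("-inf"), v
        if use_temperature:
            ll = loglik(args[0], args[1], d, v["mu"], v["sigma"])
        else:
            ll = loglik(args[0], d, v["mu"], v["sigma"])
        return lp + ll, v

    # Overdispersed but data-informed starting point with finite posterior.
    n_mean = max(float(data.n.mean()), 1.0)
    theta = None
    for _ in range(500):
        cand = []
        if use_temperature:
            cand += [rng.normal(-1.0, 1.0), rng.normal(0.0, 0.1)]
        else:
            cand.append(logit(rng.uniform(0.05, 0.95)))
        if chemical_term:
            cand.append(logit(np.exp(rng.uniform(np.log(1e-4), np.log(0.5)))))
        cand.append(np.log(n_mean * rng.uniform(0.5, 4.0) + 1.0))
        cand.append(rng.uniform(np.log(0.3), np.log(10.0)))
        cand = np.array(cand)
        lp, _ = log_posterior(cand)
        if np.isfinite(lp):
            theta = cand
            break
    if theta is None:
        raise RuntimeError("could not find a finite-likelihood starting point")

    lp_cur, v_cur = log_posterior(theta)
    # The likelihood carries a near-flat ridge (1-c)(1-d) ~ const whenever the
    # bait was applied in almost every surveyed month, so plain per-parameter
    # walks mix slowly.  An extra correlated move shifts d while holding the
    # joint survival factor (1-c)(1-d) and the implied abundance scale fixed.
    ridge = chemical_term and not use_temperature
    j_c, j_d, j_mu = 0, 1, 2
    ridge_scale = 0.5
    ridge_acc = 0.0
    ridge_n = 0
    scales = np.full(k, 0.3)
    acc_win = np.zeros(k)
    n_win = 0
    acc_post = np.zeros(k)
    n_post = 0

    def ridge_move(theta, lp_cur, v_cur, delta):
        c, d = expit(theta[j_c]), expit(theta[j_d])
        th_d_new = theta[j_d] + delta
        d_new = expit(th_d_new)
        one_minus_c_new = (1.0 - c) * (1.0 - d) / (1.0 - d_new)
        if not 0.0 < one_minus_c_new < 1.0:
            return theta, lp_cur, v_cur, False
        c_new = 1.0 - one_minus_c_new
        prop = theta.copy()
        prop[j_c] = np.log(c_new) - np.log(one_minus_c_new)
        prop[j_d] = th_d_new
        # shift log mu so the expected captures mu * qbar stay put
        q_old = loglik.capture_total(c, d).mean()
        q_new = loglik.capture_total(c_new, d_new).mean()
        if q_new <= 0.0:
            return theta, lp_cur, v_cur, False
        prop[j_mu] = theta[j_mu] + np.log(q_old / q_new)
        log_jac = (
            np.log(c) + np.log1p(-c) + np.log1p(-d)
            - np.log(c_new) - np.log1p(-c_new) - np.log1p(-d_new)
        )
        lp_prop, v_prop = log_posterior(prop)
        if np.log(rng.random()) < lp_prop - lp_cur + log_jac:
            return prop, lp_prop, v_prop, True
        return theta, lp_cur, v_cur, False

    params_out = np.empty((n_keep, k))
    N_out = np.empty((n_keep, P), dtype=np.int64)
    keep_idx = 0
    total = config.n_burnin + config.n_iter
    window = 100

    for it in range(total):
        z = rng.standard_normal(k)
        u = rng.random(k)
        for j in range(k):
            prop = theta.copy()
            prop[j] += scales[j] * z[j]
            lp_prop, v_prop = log_posterior(prop)
            if np.log(u[j]) < lp_prop - lp_cur:
                theta, lp_cur, v_cur = prop, lp_prop, v_prop
                acc_win[j] += 1
                if it >= config.n_burnin:
                    acc_post[j] += 1
        if ridge:
            theta, lp_cur, v_cur, accepted = ridge_move(
                theta, lp_cur, v_cur, ridge_scale * rng.standard_normal()
            )
            ridge_acc += accepted
            ridge_n += 1
        n_win += 1
        if it >= config.n_burnin:
            n_post += 1
        if it < config.n_burnin and n_win == window:
            rates = acc_win / n_win
            scales *= np.exp(1.2 * (rates - 0.30))
            np.clip(scales, 1e-3, 20.0, out=scales)
            acc_win[:] = 0.0
            n_win = 0
            if ridge and ridge_n:
                ridge_scale = float(
                    np.clip(ridge_scale * np.exp(1.2 * (ridge_acc / ridge_n - 0.30)), 1e-3, 20.0)
                )
                ridge_acc, ridge_n = 0.0, 0

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == config.thin - 1:
            if use_temperature:
                q = loglik.capture_total(v_cur["beta0"], v_cur["beta1"], v_cur.get("d", 0.0))
            else:
                q = loglik.capture_total(v_cur["c"], v_cur.get("d", 0.0))
            N_out[keep_idx] = sample_latent_N(
                data.n, np.clip(q, 0.0, 1.0), v_cur["mu"], v_cur["sigma"], rng
            )
            params_out[keep_idx] = [v_cur[name] for name in names]
            keep_idx += 1

    acc_rate = acc_post / max(n_post, 1)
    return params_out[:keep_idx], N_out[:keep_idx], acc_rate


def fit(
    data: CountData,
    design: SurveyDesign,
    priors: Optional[PriorSpec] = None,
    config: Optional[MCMCConfig] = None,
    use_temperature: bool = False,
    chemical_term: bool = True,
) -> PosteriorDraws:
    """Posterior sampling for the removal model.

    Runs ``config.n_chains`` independent chains from overdispersed starting
    points and returns the retained draws together with an exact conditional
    draw of every latent ``N_i`` per retained iteration.  Fully reproducible
    given ``config.seed``.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    if not (data.n > 0).any():
        # Degenerate all-zero data: c' is unidentified but the run must not crash.
        pass
    if use_temperature:
        loglik = _TemperatureLoglik(data, design, chemical_term=chemical_term)
        names = ["beta0", "beta1"]
    else:
        loglik = _ConstantLoglik(data, design, chemical_term=chemical_term)
        names = ["c"]
    if chemical_term:
        names.append("d")
    names += ["mu", "sigma"]

    seed_seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains_params, chains_N, chains_acc = [], [], []
    for ss in seed_seqs:
        p, N, acc = _run_chain(
            loglik, names, priors, config, data, use_temperature, chemical_term, ss
        )
        chains_params.append(p)
        chains_N.append(N)
        chains_acc.append(acc)
    return PosteriorDraws(
        param_names=names,
        params=np.stack(chains_params),
        N=np.stack(chains_N),
        config=config,
        rng_seed=config.seed,
        acceptance=np.stack(chains_acc),
    )


def rhat(draws: Union[PosteriorDraws, Mapping[str, np.ndarray]]) -> dict[str, float]:
    """Gelman-Rubin potential scale reduction factor per parameter.

    Uses the rank-normalized split R-hat as implemented in ``arviz``.
    Requires at least two chains with at least ten retained draws each.
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        arrays = {
            name: draws.params[:, :, j] for j, name in enumerate(draws.param_names)
        }
    else:
        arrays = {k: np.asarray(v) for k, v in draws.items()}
    for name, a in arrays.items():
        if a.ndim != 2 or a.shape[0] < 2:
            raise ValueError(
                f"R-hat for '{name}' needs >= 2 chains (shape (chains, draws)); "
                "run the sampler with n_chains >= 2"
            )
        if a.shape[1] < 10:
            raise ValueError(f"R-hat for '{name}' needs >= 10 draws per chain")
    ds = az.convert_to_dataset(arrays)
    result = az.rhat(ds)
    return {name: float(result[name].values) for name in arrays}


def _summary_row(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "ci_2.5%": float(np.quantile(x, 0.025)),
        "ci_97.5%": float(np.quantile(x, 0.975)),
    }


def summarize(draws: Union[PosteriorDraws, Mapping[str, np.ndarray]]) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval per parameter.

    For :class:`PosteriorDraws` the table also covers every latent ``N_i``
    and their total ``N_total``.
    """
    rows: dict[str, dict[str, float]] = {}
    if isinstance(draws, PosteriorDraws):
        for name in draws.param_names:
            rows[name] = _summary_row(draws.flat(name))
        flatN = draws.flat_N()
        rows["N_total"] = _summary_row(flatN.sum(axis=1))
        for i in range(draws.n_points):
            rows[f"N_{i + 1}"] = _summary_row(flatN[:, i])
    else:
        for name, x in draws.items():
            rows[name] = _summary_row(np.asarray(x, dtype=float).reshape(-1))
    return pd.DataFrame.from_dict(rows, orient="index")
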