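"""Probability machinery for the chemical-eradication removal model.

A monthly removal programme monitors a grid of points.  At each survey a
living worker may first be killed by a pesticide application (per-capita
probability ``d``) and, if it survives the application, be caught on a sticky
trap (per-capita probability ``c``).  Killed and captured individuals are
permanently removed, so the declining series of trap counts carries
information about the latent initial abundance at every point.

Within a survey death acts strictly before capture.  Writing
``phi_{t,i} = prod_{k<=t} (1 - d_{k,i})(1 - c_{k,i})`` for the joint
probability of being neither killed nor captured through survey ``t``
(``phi_0 = 1``), the joint probability of a *first removal by capture* at
survey ``t`` is::

    pi'_{t,i} = phi_{t-1,i} * (1 - d_{t,i}) * c_{t,i}

and the joint probability of a first removal by death is
``delta_{t,i} = phi_{t-1,i} * d_{t,i}``.  These partition an individual's
fate exhaustively: ``sum_t pi'_t + sum_t delta_t + phi_T = 1``.

The observation model distributes the ``n_i = sum_t y_{t,i}`` captured
individuals across surveys multinomially with cell probabilities
``pi'_{t,i} / sum_k pi'_{k,i}``; the total ``n_i`` is a binomial thinning of
the latent initial abundance ``N_i`` with success probability
``q_i = sum_k pi'_{k,i}``; and ``N_i`` is negative-binomial with mean ``mu``
and size ``sigma`` (variance ``mu + mu^2/sigma``).  Because the negative
binomial family is closed under binomial thinning, ``N_i`` can be integrated
out in closed form; :func:`marginal_loglik` uses that form.

When the pesticide term is switched off (``chemical_term=False``) the model
reduces exactly to the classic capture-only removal model with
``pi_{t,i} = prod_{k<t}(1 - c_{k,i}) * c_{t,i}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "SurveyDesign",
    "CountData",
    "ModelParams",
    "RemovalProbabilities",
    "detection_link",
    "effective_probs",
    "removal_probabilities",
    "marginal_loglik",
]


def _binary_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (surveys x points) matrix, got ndim={a.ndim}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return a.astype(np.int8)


@dataclass
class SurveyDesign:
    """Survey layout for one site.

    Parameters
    ----------
    hold
        ``(T, P)`` 0/1 matrix; 1 where the sticky trap at point ``i`` remained
        in place for survey ``t`` (lost traps have detection corrected to 0).
    chem
        ``(T, P)`` 0/1 matrix; 1 where the bait paste was applied in the month
        of survey ``t`` at point ``i``.
    temperature
        Optional length-``T`` monthly mean air temperature series (degC), used
        only when the detection probability is modelled with the
        complementary log-log temperature link.
    survey_labels
        Optional calendar labels, purely cosmetic.
    """

    hold: np.ndarray
    chem: np.ndarray
    temperature: Optional[np.ndarray] = None
    survey_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.hold = _binary_matrix(self.hold, "hold")
        self.chem = _binary_matrix(self.chem, "chem")
        if self.hold.shape != self.chem.shape:
            raise ValueError(
                f"hold {self.hold.shape} and chem {self.chem.shape} shapes differ"
            )
        if self.temperature is not None:
            t = np.asarray(self.temperature, dtype=float)
            if t.shape != (self.n_surveys,):
                raise ValueError(
                    f"temperature must have length T={self.n_surveys}, got shape {t.shape}"
                )
            self.temperature = t
        if self.survey_labels is not None and len(self.survey_labels) != self.n_surveys:
            raise ValueError("survey_labels must have length T")

    @property
    def n_surveys(self) -> int:
        return self.hold.shape[0]

    @property
    def n_points(self) -> int:
        return self.hold.shape[1]

    @classmethod
    def constant(
        cls, n_surveys: int, n_points: int, temperature=None
    ) -> "SurveyDesign":
        """All traps held and bait applied at every survey."""
        ones = np.ones((n_surveys, n_points), dtype=np.int8)
        return cls(hold=ones, chem=ones.copy(), temperature=temperature)


@dataclass
class CountData:
    """Observed removal counts: ``y[t, i]`` workers captured, ``n[i]`` totals."""

    y: np.ndarray
    n: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 2:
            raise ValueError("y must be a 2-D (surveys x points) matrix")
        if not np.issubdtype(y.dtype, np.integer):
            yi = np.rint(y).astype(np.int64)
            if not np.array_equal(yi, y):
                raise ValueError("y must contain integers")
            y = yi
        if (y < 0).any():
            raise ValueError("y must be nonnegative")
        self.y = y.astype(np.int64)
        totals = self.y.sum(axis=0)
        if self.n is None:
            self.n = totals
        else:
            n = np.asarray(self.n, dtype=np.int64)
            if not np.array_equal(n, totals):
                raise ValueError("n must equal the per-point column sums of y")
            self.n = n

    @property
    def n_surveys(self) -> int:
        return self.y.shape[0]

    @property
    def n_points(self) -> int:
        return self.y.shape[1]

    def check_consistent(self, design: SurveyDesign) -> None:
        """Validate shapes against a design and the lost-trap invariant."""
        if self.y.shape != design.hold.shape:
            raise ValueError(
                f"count matrix {self.y.shape} does not match design {design.hold.shape}"
            )
        bad = (self.y > 0) & (design.hold == 0)
        if bad.any():
            t, i = np.argwhere(bad)[0]
            raise ValueError(
                f"positive count at survey {t + 1}, point {i + 1} where the trap was lost"
            )


@dataclass
class ModelParams:
    """Parameters of the removal model.

    ``c_const`` is the per-capita monthly detection probability via a sticky
    trap; ``d_const`` the per-capita monthly death probability via the bait
    paste.  When ``use_temperature`` is set the detection probability is
    survey-specific through the complementary log-log link
    ``c'_t = 1 - exp(-exp(beta0 + beta1 * Temperature_t))`` and ``c_const`` is
    ignored.  ``mu`` and ``sigma`` are the mean and size of the negative
    binomial initial-abundance distribution (variance ``mu + mu^2/sigma``).
    With ``chemical_term=False`` the death probability is fixed at zero and
    the model reduces to the capture-only removal model.
    """

    c_const: float = 0.5
    d_const: float = 0.0
    mu: float = 10.0
    sigma: float = 1.0
    beta0: float = 0.0
    beta1: float = 0.0
    use_temperature: bool = False
    chemical_term: bool = True

    def __post_init__(self) -> None:
        if not self.use_temperature and not 0.0 < self.c_const < 1.0:
            raise ValueError("c_const must lie in (0, 1)")
        if self.chemical_term and not 0.0 <= self.d_const < 1.0:
            raise ValueError("d_const must lie in [0, 1)")
        if not (self.mu > 0 and self.sigma > 0):
            raise ValueError("mu and sigma must be positive")
        if self.use_temperature and not (
            np.isfinite(self.beta0) and np.isfinite(self.beta1)
        ):
            raise ValueError("beta0/beta1 must be finite")


@dataclass
class RemovalProbabilities:
    """Joint per-survey removal probabilities for every point.

    ``pi_prime[t, i]`` — first removal *by capture* at survey ``t``;
    ``delta[t, i]`` — first removal *by death*;
    ``phi[t, i]`` — neither killed nor captured through survey ``t``;
    ``capture_total[i] = sum_t pi_prime[t, i]`` — the binomial success
    probability linking ``n_i`` to ``N_i``.
    """

    c: np.ndarray
    d: np.ndarray
    pi_prime: np.ndarray
    delta: np.ndarray
    phi: np.ndarray
    capture_total: np.ndarray

    def conservation_gap(self) -> np.ndarray:
        """Per-point ``|1 - (sum pi' + sum delta + phi_T)|`` (should be ~0)."""
        total = self.pi_prime.sum(axis=0) + self.delta.sum(axis=0) + self.phi[-1]
        return np.abs(1.0 - total)


def detection_link(beta0, beta1, temperature):
    """Complementary log-log detection probability.

    ``1 - exp(-exp(beta0 + beta1 * temperature))``; strictly inside (0, 1)
    for finite arguments (up to floating-point rounding at the extremes).
    Accepts scalars or broadcastable arrays.
    """
    b0 = np.asarray(beta0, dtype=float)
    b1 = np.asarray(beta1, dtype=float)
    temp = np.asarray(temperature, dtype=float)
    if not (np.isfinite(b0).all() and np.isfinite(b1).all() and np.isfinite(temp).all()):
        raise ValueError("detection_link requires finite arguments")
    eta = b0 + b1 * temp
    out = -np.expm1(-np.exp(eta))
    if out.ndim == 0:
        return float(out)
    return out


def effective_probs(params: ModelParams, design: SurveyDesign):
    """Per-survey, per-point detection and death probabilities.

    Applies the lost-trap correction ``c_{t,i} = c'_t * hold_{t,i}`` and the
    bait-discontinuation correction ``d_{t,i} = d' * chem_{t,i}``.  Note that
    a lost trap zeroes *detection only*: the bait can still kill that month.
    """
    if params.use_temperature:
        if design.temperature is None:
            raise ValueError(
                "use_temperature is set but the design carries no temperature series"
            )
        c_prime = detection_link(params.beta0, params.beta1, design.temperature)
        c = np.asarray(c_prime)[:, None] * design.hold
    else:
        c = params.c_const * design.hold.astype(float)
    d_prime = params.d_const if params.chemical_term else 0.0
    d = d_prime * design.chem.astype(float)
    return c, d


def _as_prob_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 1-D or 2-D")
    if ((a < 0) | (a > 1)).any() or not np.isfinite(a).all():
        raise ValueError(f"{name} entries must lie in [0, 1]")
    return a


def removal_probabilities(c, d) -> RemovalProbabilities:
    """Joint first-removal probabilities from per-survey ``c`` and ``d``.

    Both arguments are ``(T, P)`` matrices (a 1-D vector is treated as a
    single point).  All joint products are computed in log space to avoid
    underflow over long horizons; the exhaustive-partition identity
    ``sum pi' + sum delta + phi_T = 1`` then holds per point to ~1e-15.
    """
    c = _as_prob_matrix(c, "c")
    d = _as_prob_matrix(d, "d")
    if c.shape != d.shape:
        raise ValueError(f"c {c.shape} and d {d.shape} shapes differ")
    T, P = c.shape
    with np.errstate(divide="ignore"):
        log_qc = np.log1p(-c)
        log_qd = np.log1p(-d)
        log_c = np.log(c)
        log_d = np.log(d)
    log_phi = np.cumsum(log_qc + log_qd, axis=0)
    log_phi_prev = np.vstack([np.zeros((1, P)), log_phi[:-1]])
    phi = np.exp(log_phi)
    # -inf sums stay -inf; exp maps them to exact zeros.
    pi_prime = np.exp(log_phi_prev + log_qd + log_c)
    delta = np.exp(log_phi_prev + log_d)
    return RemovalProbabilities(
        c=c,
        d=d,
        pi_prime=pi_prime,
        delta=delta,
        phi=phi,
        capture_total=pi_prime.sum(axis=0),
    )


def _thinned_negbin_logpmf(n: np.ndarray, q: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """log pmf of ``n_i`` with ``N_i`` integrated out.

    ``N ~ NegBin(mean mu, size sigma)`` followed by binomial thinning with
    keep probability ``q`` is again negative binomial with the same size and
    success probability ``p' = p / (p + q(1-p))`` where ``p = sigma/(sigma+mu)``.
    """
    r = sigma
    p = r / (r + mu)
    a = p + q * (1.0 - p)  # 1 - (1-p)(1-q)
    p_thin = p / a
    return (
        gammaln(n + r)
        - gammaln(r)
        - gammaln(n + 1)
        + r * np.log(p_thin)
        + xlogy(n, 1.0 - p_thin)
    )


def marginal_loglik(
    params: ModelParams,
    design: SurveyDesign,
    data: CountData,
    strict: bool = True,
) -> float:
    """Log marginal likelihood with the latent abundances integrated out.

    Per point the likelihood factorises as a multinomial over surveys
    (conditional on ``n_i``) times the thinned-negative-binomial marginal of
    ``n_i``.  Impossible data — a positive count at a survey whose cell
    probability is zero, or ``n_i > 0`` at a point whose total capture
    probability is zero — yield ``-inf`` rather than an exception so that a
    sampler can reject the move.
    """
    if strict:
        data.check_consistent(design)
    elif data.y.shape != design.hold.shape:
        raise ValueError("count matrix does not match design shape")
    c, d = effective_probs(params, design)
    rp = removal_probabilities(c, d)
    y, n = data.y, data.n
    q = rp.capture_total

    if ((y > 0) & (rp.pi_prime == 0.0)).any():
        return float("-inf")
    if ((n > 0) & (q == 0.0)).any():
        return float("-inf")

    mult = (
        xlogy(y, rp.pi_prime).sum()
        - xlogy(n, q).sum()
        + gammaln(n + 1).sum()
        - gammaln(y + 1).sum()
    )
    marg = _thinned_negbin_logpmf(n, q, params.mu, params.sigma).sum()
    return float(mult + marg)
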