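"""Posterior survivor trajectories and eradication-declaration criteria.

For every retained posterior draw the joint probability of an individual
being neither killed nor captured through survey ``t`` is
``phi_{t,i} = prod_{k<=t} (1 - d_{k,i})(1 - c_{k,i})``; the survivor count at
point ``i`` is then a fresh binomial draw ``s_{t,i} ~ Bin(N_i, phi_{t,i})``
(a marginal construction: survivor counts are not constrained to be
monotone within a draw).  The site-level presence probability is
``Ps_t = Pr(S_t >= 1)`` with ``S_t = sum_i s_{t,i}``, and eradication is
declared at the 95% (99%) level in the first month after which ``Ps_t``
stays below 0.05 (0.01).

Note on conventions: the quantity driving declaration is the probability
that at least one ant is still alive (presence), so eradication corresponds
to ``Ps_t`` falling and staying *below* the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .inference import PosteriorDraws
from .model_core import SurveyDesign, detection_link

__all__ = [
    "SurvivorDraws",
    "EradicationSummary",
    "survivor_draws",
    "presence_probability",
    "declaration_times",
    "eradication_summary",
]


@dataclass
class SurvivorDraws:
    """Posterior survivor counts: ``s`` is ``(draws, T, P)``, ``S = sum_i s``."""

    s: np.ndarray
    S: np.ndarray


def _survival_logprob(
    draws: PosteriorDraws, design: SurveyDesign, sl: slice
) -> np.ndarray:
    """log phi for a chunk of flattened draws: shape (chunk, T, P)."""
    flat = draws.flat_params()[sl]
    names = draws.param_names
    T = design.n_surveys
    if "c" in names:
        c_prime = np.broadcast_to(
            flat[:, names.index("c")][:, None], (flat.shape[0], T)
        )
    else:
        b0 = flat[:, names.index("beta0")][:, None]
        b1 = flat[:, names.index("beta1")][:, None]
        c_prime = detection_link(b0, b1, design.temperature[None, :])
    d_prime = (
        flat[:, names.index("d")] if "d" in names else np.zeros(flat.shape[0])
    )
    hold = design.hold.astype(float)
    chem = design.chem.astype(float)
    with np.errstate(divide="ignore"):
        lq_c = np.log1p(-c_prime)[:, :, None] * hold[None, :, :]
        lq_d = np.log1p(-d_prime)[:, None, None] * chem[None, :, :]
    return np.cumsum(lq_c + lq_d, axis=1)


def survivor_draws(
    posterior: PosteriorDraws,
    design: SurveyDesign,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    chunk: int = 512,
) -> SurvivorDraws:
    """Draw ``s_{t,i} ~ Bin(N_i, phi_{t,i})`` for every retained draw."""
    if posterior.n_points != design.n_points:
        raise ValueError(
            f"posterior has {posterior.n_points} points but design has {design.n_points}"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_total = posterior.n_chains * posterior.n_draws
    T, P = design.n_surveys, design.n_points
    flatN = posterior.flat_N()
    s = np.empty((n_total, T, P), dtype=np.int64)
    for start in range(0, n_total, chunk):
        sl = slice(start, min(start + chunk, n_total))
        phi = np.exp(_survival_logprob(posterior, design, sl))
        s[sl] = rng.binomial(flatN[sl][:, None, :], phi)
    return SurvivorDraws(s=s, S=s.sum(axis=2))


def presence_probability(survivors: SurvivorDraws) -> np.ndarray:
    """``Ps_t``: fraction of posterior draws with at least one survivor."""
    if survivors.S.size == 0:
        raise ValueError("no survivor draws")
    return (survivors.S >= 1).mean(axis=0)


def declaration_times(
    Ps: Sequence[float], thresholds: Sequence[float] = (0.05, 0.01)
) -> dict[float, Optional[int]]:
    """First month (1-based) after which ``Ps`` stays below each threshold.

    The crossing must be sustained: every later month must also be below the
    threshold, so isolated Monte-Carlo blips do not trigger a declaration.
    A threshold never sustainedly crossed maps to ``None`` ("not yet
    eradicated").
    """
    Ps = np.asarray(Ps, dtype=float)
    if ((Ps < 0) | (Ps > 1)).any() or not np.isfinite(Ps).all():
        raise ValueError("Ps entries must lie in [0, 1]")
    out: dict[float, Optional[int]] = {}
    for thr in thresholds:
        above = np.nonzero(Ps >= thr)[0]
        if above.size == 0:
            out[thr] = 1
        elif above[-1] == Ps.size - 1:
            out[thr] = None
        else:
            out[thr] = int(above[-1]) + 2  # 1-based month after the last exceedance
    return out


@dataclass
class EradicationSummary:
    """Presence-probability series with the 95%/99% declaration months."""

    Ps: np.ndarray
    t95: Optional[int]
    t99: Optional[int]
    last_detection_month: Optional[int] = None

    @property
    def months_since_last_detection(self) -> dict[str, Optional[int]]:
        if self.last_detection_month is None:
            return {"t95": None, "t99": None}
        return {
            "t95": None if self.t95 is None else self.t95 - self.last_detection_month,
            "t99": None if self.t99 is None else self.t99 - self.last_detection_month,
        }


def eradication_summary(
    Ps: Sequence[float], last_detection_month: Optional[int] = None
) -> EradicationSummary:
    """Declaration months at the 0.05 and 0.01 presence thresholds."""
    times = declaration_times(Ps, thresholds=(0.05, 0.01))
    return EradicationSummary(
        Ps=np.asarray(Ps, dtype=float),
        t95=times[0.05],
        t99=times[0.01],
        last_detection_month=last_detection_month,
    )
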