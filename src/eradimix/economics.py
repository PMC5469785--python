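"""Net expected cost of declaring eradication and the optimal stopping month.

Declaring eradication after ``m`` consecutive detection-free months costs

    NEC(m) = (m - 1) * Cs + presence(m) * Ce

where ``Cs`` is the monthly monitoring cost, ``Ce`` the cost of escape and
damage if ants persist after the declaration, and ``presence(m)`` the
posterior probability that ants are still present despite ``m`` months
without detection.  The optimal stopping month minimises the curve; ties are
broken toward the earlier month.  ``presence(m)`` is read from the
eradication module's ``Ps`` series at calendar month
``last_detection + m`` (``m = 1`` is the first monitoring month after the
last sighting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NECCurve",
    "nec",
    "optimal_stopping",
    "sensitivity",
    "presence_after_last_sighting",
]


@dataclass
class NECCurve:
    """NEC(m) over a month range with its minimiser."""

    m: np.ndarray
    nec: np.ndarray
    m_opt: int
    nec_min: float
    presence: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": self.m, "presence": self.presence, "nec": self.nec})


def nec(m: int, Cs: float, Ce: float, presence: float) -> float:
    """Net expected cost of declaring eradication after ``m`` quiet months."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if Cs <= 0 or Ce < 0:
        raise ValueError("need Cs > 0 and Ce >= 0")
    if not 0.0 <= presence <= 1.0:
        raise ValueError("presence must lie in [0, 1]")
    return (m - 1) * Cs + presence * Ce


def optimal_stopping(
    presence_given_m: Sequence[float],
    Cs: float,
    Ce: float,
    extra_monthly_cost: Optional[Sequence[float]] = None,
) -> NECCurve:
    """Full NEC curve and its argmin over ``m = 1 .. len(presence_given_m)``.

    ``extra_monthly_cost`` is an optional surcharge vector aligned to months
    since the last sighting (e.g. continued pesticide applications for the
    first six months); month ``k``'s surcharge accrues, like ``Cs``, only if
    monitoring continues past it, i.e. in NEC(m) for ``m > k``.
    """
    presence = np.asarray(presence_given_m, dtype=float)
    if presence.size == 0:
        raise ValueError("presence_given_m must be non-empty")
    if ((presence < 0) | (presence > 1)).any():
        raise ValueError("presence values must lie in [0, 1]")
    if Cs <= 0 or Ce < 0:
        raise ValueError("need Cs > 0 and Ce >= 0")
    m = np.arange(1, presence.size + 1)
    monthly = np.full(presence.size, float(Cs))
    if extra_monthly_cost is not None:
        extra = np.asarray(extra_monthly_cost, dtype=float)
        monthly[: extra.size] += extra[: presence.size]
    accrued = np.concatenate([[0.0], np.cumsum(monthly)[:-1]])  # cost before month m
    values = accrued + presence * Ce
    j = int(np.argmin(values))  # argmin returns the first minimiser: earlier month wins
    return NECCurve(
        m=m, nec=values, m_opt=int(m[j]), nec_min=float(values[j]), presence=presence
    )


def sensitivity(
    Cs: float,
    ratios: Sequence[float],
    presence_given_m: Sequence[float],
    extra_monthly_cost: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Optimal stopping month for a grid of escape-to-monitoring cost ratios.

    ``Ce = ratio * Cs`` per row.  For a non-increasing presence series the
    optimal month is non-decreasing in the ratio.
    """
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ValueError("cost ratios must be positive")
    rows = []
    for r in ratios:
        curve = optimal_stopping(
            presence_given_m, Cs, r * Cs, extra_monthly_cost=extra_monthly_cost
        )
        rows.append({"ratio": float(r), "m_opt": curve.m_opt, "nec_min": curve.nec_min})
    return pd.DataFrame(rows)


def presence_after_last_sighting(
    Ps: Sequence[float], last_detection_month: int
) -> np.ndarray:
    """Presence probability indexed by months since the last sighting.

    Month ``m = 1`` maps to the calendar month ``last_detection_month + 1``
    of the ``Ps`` series (1-based).
    """
    Ps = np.asarray(Ps, dtype=float)
    if not 1 <= last_detection_month <= Ps.size:
        raise ValueError("last_detection_month outside the Ps series")
    return Ps[last_detection_month:]
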