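"""Survey-table file formats and validation.

The long-format survey CSV carries one row per (site, point, month):
columns ``site, point_id, month_index, count, hold, chem`` plus optional
``calendar_label`` and ``temperature``.  Month indices are 1-based and must
be gapless per site after any exclusions are dropped (e.g. a first survey
whose traps were lost); indices are re-based after exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import CountData, SurveyDesign

__all__ = ["SiteRecord", "read_survey", "write_survey", "site_to_frame", "combine_sites"]

REQUIRED_COLUMNS = ("site", "point_id", "month_index", "count", "hold", "chem")


@dataclass
class SiteRecord:
    """In-memory survey data for one site."""

    site: str
    design: SurveyDesign
    data: CountData
    point_ids: list
    month_index: np.ndarray  # original (pre-rebase) 1-based month indices


def _validation_error(frame: pd.DataFrame, mask: np.ndarray, message: str) -> ValueError:
    rows = frame.index[np.asarray(mask)].tolist()[:5]
    return ValueError(f"{message} (rows {rows})")


def read_survey(
    path, exclusions: Optional[Sequence[int]] = None
) -> dict[str, SiteRecord]:
    """Read and validate a long-format survey CSV, one record per site.

    ``exclusions`` lists 1-based month indices to drop before fitting (the
    remaining months are re-based to a gapless 1..T).  Raises ``ValueError``
    with row-level context on schema violations.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"survey table is missing columns {missing}")
    for col in ("count", "hold", "chem", "month_index"):
        if frame[col].isna().any():
            raise _validation_error(frame, frame[col].isna(), f"missing values in '{col}'")
        if not np.array_equal(frame[col], frame[col].astype(np.int64)):
            raise _validation_error(
                frame, frame[col] != frame[col].astype(np.int64), f"non-integer '{col}'"
            )
    frame = frame.astype(
        {"count": np.int64, "hold": np.int64, "chem": np.int64, "month_index": np.int64}
    )
    if (frame["count"] < 0).any():
        raise _validation_error(frame, frame["count"] < 0, "negative count")
    for col in ("hold", "chem"):
        bad = ~frame[col].isin((0, 1))
        if bad.any():
            raise _validation_error(frame, bad, f"non-binary '{col}'")
    bad = (frame["count"] > 0) & (frame["hold"] == 0)
    if bad.any():
        raise _validation_error(frame, bad, "positive count where the trap was lost (hold = 0)")
    dup = frame.duplicated(subset=["site", "point_id", "month_index"])
    if dup.any():
        raise _validation_error(frame, dup, "duplicate (site, point_id, month_index) key")

    if exclusions:
        frame = frame[~frame["month_index"].isin(list(exclusions))]
        if frame.empty:
            raise ValueError("all months excluded")

    out: dict[str, SiteRecord] = {}
    for site, g in frame.groupby("site", sort=True):
        months = np.sort(g["month_index"].unique())
        points = sorted(g["point_id"].unique())
        # gapless after exclusion: a consecutive run of whatever indices remain
        expected = np.arange(months[0], months[0] + months.size)
        if exclusions:
            kept = [
                m
                for m in range(months.min(), months.max() + 1)
                if m not in set(exclusions)
            ]
            if list(months) != kept:
                raise ValueError(
                    f"site {site}: month indices have gaps beyond the exclusion list"
                )
        elif not np.array_equal(months, expected):
            raise ValueError(f"site {site}: month_index must be gapless")
        T, P = months.size, len(points)
        m_pos = {m: k for k, m in enumerate(months)}
        p_pos = {p: k for k, p in enumerate(points)}
        y = np.zeros((T, P), dtype=np.int64)
        hold = np.zeros((T, P), dtype=np.int8)
        chem = np.zeros((T, P), dtype=np.int8)
        temp = np.full(T, np.nan) if "temperature" in g.columns else None
        seen = np.zeros((T, P), dtype=bool)
        for row in g.itertuples(index=False):
            t, i = m_pos[row.month_index], p_pos[row.point_id]
            y[t, i] = row.count
            hold[t, i] = row.hold
            chem[t, i] = row.chem
            seen[t, i] = True
            if temp is not None:
                temp[t] = getattr(row, "temperature")
        if not seen.all():
            t, i = np.argwhere(~seen)[0]
            raise ValueError(
                f"site {site}: missing row for month {months[t]}, point {points[i]}"
            )
        temperature = None
        if temp is not None and np.isfinite(temp).all():
            temperature = temp
        design = SurveyDesign(hold=hold, chem=chem, temperature=temperature)
        out[str(site)] = SiteRecord(
            site=str(site),
            design=design,
            data=CountData(y=y),
            point_ids=points,
            month_index=months,
        )
    return out


def combine_sites(parts):
    """Pool several sites surveyed over the same months into one design.

    The removal model shares the detection and death probabilities across
    the whole programme, so multi-site data are fitted jointly by stacking
    the sites' points side by side.  Returns ``(design, data, slices)``
    where ``slices[k]`` selects site ``k``'s columns in the pooled arrays.

    ``parts`` is a sequence of ``(SurveyDesign, CountData)`` pairs with a
    common number of surveys.
    """
    designs = [p[0] for p in parts]
    datas = [p[1] for p in parts]
    T = designs[0].n_surveys
    if any(d.n_surveys != T for d in designs):
        raise ValueError("all sites must cover the same survey months")
    design = SurveyDesign(
        hold=np.hstack([d.hold for d in designs]),
        chem=np.hstack([d.chem for d in designs]),
        temperature=designs[0].temperature,
    )
    data = CountData(y=np.hstack([d.y for d in datas]))
    slices, start = [], 0
    for d in designs:
        slices.append(slice(start, start + d.n_points))
        start += d.n_points
    return design, data, slices


def site_to_frame(
    design: SurveyDesign,
    data: CountData,
    site: str = "site1",
    point_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Long-format survey table for one site."""
    T, P = design.n_surveys, design.n_points
    if point_ids is None:
        point_ids = [f"p{i + 1:03d}" for i in range(P)]
    t_idx, p_idx = np.meshgrid(np.arange(T), np.arange(P), indexing="ij")
    frame = pd.DataFrame(
        {
            "site": site,
            "point_id": np.asarray(point_ids, dtype=object)[p_idx.ravel()],
            "month_index": (t_idx.ravel() + 1).astype(np.int64),
            "count": data.y.ravel(),
            "hold": design.hold.ravel().astype(np.int64),
            "chem": design.chem.ravel().astype(np.int64),
        }
    )
    if design.temperature is not None:
        frame["temperature"] = design.temperature[t_idx.ravel()]
    return frame


def write_survey(path, records) -> None:
    """Write one or more sites back to the long-format CSV.

    ``records`` may be the dict returned by :func:`read_survey` or a single
    :class:`SiteRecord`.
    """
    if isinstance(records, SiteRecord):
        records = {records.site: records}
    frames = []
    for site, rec in records.items():
        f = site_to_frame(rec.design, rec.data, site=site, point_ids=rec.point_ids)
        f["month_index"] = rec.month_index[f["month_index"] - 1]
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
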