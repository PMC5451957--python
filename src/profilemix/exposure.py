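"""Residential-proximity pesticide-use estimates from application records.

The exposure model: draw a disk of configurable radius (default 1 km)
around each maternal residence, weight the kilograms applied in each
one-square-mile section by the fraction of the section's area inside the
disk, sum within each pregnancy trimester (requiring a minimum number of
days of known residential location per trimester), and average the
qualifying trimesters over the pregnancy.  Continuous estimates are then
filtered for sufficient use/contrast and discretised into quartile
categories 1..4, forming the profiles consumed by the clustering model.

Coordinates are consumed already projected to planar metres; no CRS
handling happens here.  Date intervals (occupancy and trimesters) are
closed on both ends; an application dated on a shared boundary counts once,
to the earlier interval.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureTable",
    "buffer_section_weight",
    "section_weights",
    "trimester_use",
    "pregnancy_average",
    "inclusion_filter",
    "quartile_discretize",
    "build_exposure_table",
]

#: Segments per quarter circle in the disk approximation. 512 total
#: segments keep the polygonal-disk area error ~2.5e-5 relative.
BUFFER_QUAD_SEGS = 128


def _as_polygon(section) -> Polygon:
    if isinstance(section, Polygon):
        return section
    x0, y0, x1, y1 = section  # bounding box tuple
    return box(x0, y0, x1, y1)


def buffer_section_weight(
    residence_xy: tuple[float, float],
    section,
    radius_m: float,
    quad_segs: int = BUFFER_QUAD_SEGS,
) -> float:
    """Fraction of a section's land area inside the residence buffer.

    ``section`` may be a shapely Polygon or an (xmin, ymin, xmax, ymax)
    tuple.  Returns area(section ∩ disk(residence, radius)) / area(section).
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    poly = _as_polygon(section)
    if poly.area == 0:
        raise ValueError("section polygon has zero area")
    disk = Point(*residence_xy).buffer(radius_m, quad_segs=quad_segs)
    return float(poly.intersection(disk).area / poly.area)


def section_weights(
    residence_xy: tuple[float, float],
    sections: Mapping[str, object],
    radius_m: float,
) -> dict[str, float]:
    """Buffer weights for every section overlapping the disk (weight > 0)."""
    x, y = residence_xy
    out = {}
    for sid, sec in sections.items():
        poly = _as_polygon(sec)
        x0, y0, x1, y1 = poly.bounds
        # cheap bounding-box reject before exact geometry
        if x0 - radius_m > x or x1 + radius_m < x or y0 - radius_m > y or y1 + radius_m < y:
            continue
        w = buffer_section_weight(residence_xy, poly, radius_m)
        if w > 0:
            out[sid] = w
    return out


def _overlap_days(s1, e1, s2, e2) -> int:
    """Days in [s1,e1] ∩ [s2,e2], both intervals closed."""
    lo, hi = max(s1, s2), min(e1, e2)
    return max(0, (hi - lo).days + 1)


def _check_residences(res: pd.DataFrame, subject: str) -> pd.DataFrame:
    res = res.sort_values("start_date")
    starts = res["start_date"].to_numpy()
    ends = res["end_date"].to_numpy()
    if (ends < starts).any():
        raise ValueError(f"residence window with end < start for {subject}")
    if len(res) > 1 and (starts[1:] <= ends[:-1]).any():
        raise ValueError(
            f"overlapping residence windows for {subject}: location ambiguous"
        )
    return res


def trimester_use(
    records: pd.DataFrame,
    residence_windows: pd.DataFrame,
    pregnancy: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    chemical: str,
    sections: Mapping[str, object],
    radius_m: float = 1000.0,
) -> list[tuple[float, int]]:
    """Per-trimester (kg estimate, days of known residence) for one subject.

    ``records`` are application records (section_id, date, chemical, kg);
    ``residence_windows`` the subject's occupancy windows; ``pregnancy`` the
    three ordered closed trimester intervals.
    """
    res = _check_residences(residence_windows, str(residence_windows.get("subject_id", pd.Series(["?"])).iloc[0]))
    recs = records[records["chemical"] == chemical]
    out = []
    prev_end = None
    for t_start, t_end in pregnancy:
        kg = 0.0
        days = 0
        for _, rw in res.iterrows():
            days += _overlap_days(rw["start_date"], rw["end_date"], t_start, t_end)
            lo = max(rw["start_date"], t_start)
            hi = min(rw["end_date"], t_end)
            if lo > hi:
                continue
            in_win = recs[(recs["date"] >= lo) & (recs["date"] <= hi)]
            if prev_end is not None and lo == prev_end:
                # boundary date shared with the previous trimester: counts
                # once, to the earlier interval
                in_win = in_win[in_win["date"] > lo]
            if in_win.empty:
                continue
            ws = section_weights((rw["x_m"], rw["y_m"]), sections, radius_m)
            w = in_win["section_id"].map(ws).fillna(0.0)
            kg += float((in_win["kg"] * w).sum())
        out.append((kg, days))
        prev_end = t_end
    return out


def pregnancy_average(
    per_trimester: Sequence[tuple[float, int]],
    min_days: int = 75,
    min_trimesters: int = 2,
) -> float | None:
    """Average use over qualifying trimesters, or None ("insufficient").

    A trimester qualifies if its days of known residential location reach
    ``min_days``; subjects with fewer than ``min_trimesters`` qualifying
    trimesters are excluded (None).
    """
    if not 1 <= len(per_trimester) <= 3:
        raise ValueError("expected 1-3 trimester entries")
    qual = [kg for kg, days in per_trimester if days >= min_days]
    if len(qual) < min_trimesters:
        return None
    return float(sum(qual) / len(qual))


def inclusion_filter(exposure_matrix: pd.DataFrame) -> list[str]:
    """Pesticides with population median > 0 and >= two-fold IQR contrast.

    A pesticide is retained iff its median estimate is above zero and its
    75th percentile is at least twice its 25th percentile (inclusive; with
    q25 = 0 and median > 0 the contrast is infinite and the criterion is
    satisfied).  Returns names in input column order.
    """
    if exposure_matrix.shape[0] == 0 or exposure_matrix.shape[1] == 0:
        raise ValueError("empty exposure matrix")
    if exposure_matrix.shape[0] < 4:
        raise ValueError("need at least 4 subjects for quartile contrast")
    kept = []
    for col in exposure_matrix.columns:
        v = exposure_matrix[col].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        if med > 0 and q75 >= 2.0 * q25:
            kept.append(col)
    return kept


def quartile_discretize(column) -> tuple[np.ndarray, np.ndarray]:
    """Quartile categories 1..4 and the (q25, q50, q75) cut points.

    Cut points use the linear-interpolation percentile definition; bins are
    half-open: (-inf, q25], (q25, q50], (q50, q75], (q75, inf).  Tied mass
    collapses categories deterministically (an all-equal column maps to
    category 1 everywhere, with a warning).
    """
    v = np.asarray(column, dtype=float)
    cuts = np.percentile(v, [25, 50, 75])
    if cuts[0] == cuts[2] and np.all(v == v[0]):
        warnings.warn("constant column: all observations in category 1")
    cats = (v[:, None] > cuts[None, :]).sum(axis=1) + 1
    return cats.astype(np.int64), cuts


@dataclasses.dataclass
class ExposureTable:
    """Continuous pregnancy-average estimates plus quartile profiles."""

    continuous: pd.DataFrame  # subjects x retained pesticides, kg
    cumulative: pd.Series  # per-subject row sum over retained pesticides
    quartile_profiles: pd.DataFrame  # same shape, categories 1..4
    cut_points: dict[str, np.ndarray]  # pesticide -> (q25, q50, q75)
    cumulative_cut_points: np.ndarray
    retained: list[str]
    excluded: list[str]
    insufficient_subjects: list[str]

    def to_csv(self, path: str | Path) -> None:
        df = pd.concat(
            [
                self.continuous,
                self.quartile_profiles.add_suffix("_q"),
                self.cumulative.rename("cumulative"),
            ],
            axis=1,
        )
        df.to_csv(path, index_label="subject_id")


def build_exposure_table(
    applications: pd.DataFrame,
    residences: pd.DataFrame,
    pregnancies: pd.DataFrame,
    sections: Mapping[str, object],
    radius_m: float = 1000.0,
    min_days: int = 75,
    min_trimesters: int = 2,
    chemicals: Sequence[str] | None = None,
    apply_filter: bool = True,
) -> ExposureTable:
    """Full exposure-assessment chain for a study population.

    ``applications``: section_id/date/chemical/kg rows. ``residences``:
    subject_id/x_m/y_m/start_date/end_date. ``pregnancies``: subject_id plus
    t{1,2,3}_{start,end} columns.  Subjects failing the minimum-trimester
    criterion are dropped (and listed); pesticides failing the inclusion
    filter are dropped unless ``apply_filter`` is False.
    """
    apps = applications.copy()
    apps["date"] = pd.to_datetime(apps["date"])
    if (apps["kg"] < 0).any():
        raise ValueError("application kg must be non-negative")
    res = residences.copy()
    for c in ("start_date", "end_date"):
        res[c] = pd.to_datetime(res[c])
    preg = pregnancies.copy()
    for c in preg.columns:
        if c != "subject_id":
            preg[c] = pd.to_datetime(preg[c])

    chems = list(chemicals) if chemicals is not None else sorted(apps["chemical"].unique())
    apps = apps[apps["chemical"].isin(chems)]
    apps_by_chem = {c: g for c, g in apps.groupby("chemical")}
    empty_apps = apps.iloc[:0]

    rows = {}
    insufficient = []
    preg = preg.set_index("subject_id")
    for sid, subj_res in res.groupby("subject_id", sort=True):
        subj_res = _check_residences(subj_res, str(sid))
        pr = preg.loc[sid]
        tri = [
            (pr[f"t{k}_start"], pr[f"t{k}_end"]) for k in (1, 2, 3)
        ]
        for a, b in tri:
            if b < a:
                raise ValueError(f"trimester end before start for {sid}")
        # precompute weights per residence window once
        win_weights = [
            section_weights((rw["x_m"], rw["y_m"]), sections, radius_m)
            for _, rw in subj_res.iterrows()
        ]
        # restrict each chemical's records to sections this subject's
        # buffers touch, once per subject
        touched = set()
        for ws in win_weights:
            touched.update(ws)
        apps_near = {
            c: g[g["section_id"].isin(touched)]
            for c, g in apps_by_chem.items()
        }
        est = {}
        for chem in chems:
            chem_apps = apps_near.get(chem, empty_apps)
            per_tri = []
            prev_end = None
            for t_start, t_end in tri:
                kg = 0.0
                days = 0
                for (_, rw), ws in zip(subj_res.iterrows(), win_weights):
                    days += _overlap_days(rw["start_date"], rw["end_date"], t_start, t_end)
                    lo = max(rw["start_date"], t_start)
                    hi = min(rw["end_date"], t_end)
                    if lo > hi:
                        continue
                    sel = chem_apps[
                        (chem_apps["date"] >= lo) & (chem_apps["date"] <= hi)
                    ]
                    if prev_end is not None and lo == prev_end:
                        sel = sel[sel["date"] > lo]
                    if sel.empty:
                        continue
                    w = sel["section_id"].map(ws).fillna(0.0)
                    kg += float((sel["kg"] * w).sum())
                per_tri.append((kg, days))
                prev_end = t_end
            avg = pregnancy_average(per_tri, min_days, min_trimesters)
            if avg is None:
                insufficient.append(str(sid))
                est = None
                break
            est[chem] = avg
        if est is not None:
            rows[str(sid)] = est

    if not rows:
        raise ValueError("no subject met the minimum-trimester criterion")
    continuous = pd.DataFrame.from_dict(rows, orient="index")[chems]

    if apply_filter:
        retained = inclusion_filter(continuous)
    else:
        retained = chems
    excluded = [c for c in chems if c not in retained]
    if excluded:
        logger.info("inclusion filter dropped: %s", ", ".join(excluded))
    continuous = continuous[retained]
    cumulative = continuous.sum(axis=1).rename("cumulative")

    cats = {}
    cut_points = {}
    for col in retained:
        c, q = quartile_discretize(continuous[col])
        cats[col] = c
        cut_points[col] = q
    quartiles = pd.DataFrame(cats, index=continuous.index)[retained]
    _, cum_cuts = quartile_discretize(cumulative)
    return ExposureTable(
        continuous=continuous,
        cumulative=cumulative,
        quartile_profiles=quartiles,
        cut_points=cut_points,
        cumulative_cut_points=cum_cuts,
        retained=retained,
        excluded=excluded,
        insufficient_subjects=sorted(set(insufficient)),
    )
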