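"""Cohort-level aggregation and statistics for trajectory measurements.

The cohort table holds one row per (subject, side) with the axial and
coronal approach angles, the sphenoid-ridge angle, and the AC-PC
coordinates of the limen insulae and the target.  On top of it sit the
study's analyses: per-plane summaries, right-left paired t-tests, the
approach-angle/ridge-angle correlation, and the ±10° parallelism count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coordinate_frames import (
    HemisphereSide,
    apply_transform,
    fit_acpc_transform,
)
from .errors import StatisticsError
from .landmark_io import LandmarkSet
from .trajectory_geometry import (
    ApproachVector,
    SphenoidRidgeLine,
    compute_approach_angles,
    compute_sphenoid_angle,
    compute_target_point,
)

__all__ = [
    "COHORT_COLUMNS",
    "SummaryStats",
    "PairedTestResult",
    "CorrelationResult",
    "ParallelismResult",
    "summarize",
    "paired_t_test",
    "correlate",
    "parallelism_analysis",
    "build_cohort_table",
    "write_cohort_table",
    "read_cohort_table",
]

COHORT_COLUMNS = (
    "subject_id",
    "side",
    "theta_a",
    "theta_c",
    "sphenoid_angle",
    "limen_x",
    "limen_y",
    "limen_z",
    "target_x",
    "target_y",
    "target_z",
)


@dataclass(frozen=True)
class SummaryStats:
    """Sample summary of a list of angles (sd uses the n-1 denominator)."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    range: float


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    mean_difference: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ParallelismResult:
    n_within: int
    n_total: int
    proportion: float
    tolerance: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample sd, min, max and range of a nonempty list of angles.

    With a single value the sd is undefined; it is reported as 0.0 and the
    n field (== 1) flags the degenerate case.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise StatisticsError("cannot summarize an empty list")
    if not np.isfinite(arr).all():
        raise StatisticsError("summarize requires finite values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    vmin, vmax = float(arr.min()), float(arr.max())
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=vmin,
        max=vmax,
        range=vmax - vmin,
    )


def paired_t_test(
    right: Sequence[float], left: Sequence[float], alpha: float = 0.01
) -> PairedTestResult:
    """Two-sided paired t-test on right-minus-left differences.

    Pairs are matched by position (subject order).  The test statistic is
    t = d̄ / (s_d / √n) on n-1 degrees of freedom.
    """
    r = np.asarray(list(right), dtype=float)
    l = np.asarray(list(left), dtype=float)
    if r.shape != l.shape:
        raise StatisticsError(
            f"paired samples differ in length: {r.size} vs {l.size}"
        )
    if r.size < 2:
        raise StatisticsError("paired t-test needs at least 2 pairs")
    d = r - l
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise StatisticsError(
            "differences have zero variance; the paired t statistic is undefined"
        )
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedTestResult(
        n_pairs=n,
        mean_difference=float(d.mean()),
        t_statistic=t,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    The p-value follows the t approximation t = r √((n-2)/(1-r²)) on n-2
    degrees of freedom (for |r| = 1 the p-value is 0).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise StatisticsError(f"samples differ in length: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise StatisticsError("correlation needs at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise StatisticsError("correlation is undefined for a constant sample")
    if method == "spearman":
        xa = sps.rankdata(xa)
        ya = sps.rankdata(ya)
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    n = xa.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(method=method, r=r, p_value=p, n=n)


def parallelism_analysis(
    table: pd.DataFrame, tolerance: float = 10.0
) -> ParallelismResult:
    """Count trajectories whose axial angle lies within ±tolerance of the ridge.

    The boundary is inclusive: an offset of exactly ±tolerance counts as
    within.  The proportion is a percentage of all rows.
    """
    if len(table) == 0:
        raise StatisticsError("parallelism analysis needs a nonempty cohort table")
    offsets = np.asarray(table["theta_a"], float) - np.asarray(
        table["sphenoid_angle"], float
    )
    if not np.isfinite(offsets).all():
        raise StatisticsError("parallelism analysis requires finite angles")
    n_within = int((np.abs(offsets) <= tolerance).sum())
    n_total = int(len(offsets))
    return ParallelismResult(
        n_within=n_within,
        n_total=n_total,
        proportion=100.0 * n_within / n_total,
        tolerance=float(tolerance),
    )


def _measure_one(lset: LandmarkSet) -> dict:
    required = [
        "AC",
        "PC",
        "limen_insulae",
        "hippocampal_sulcus",
        "innominate_sulcus",
        "sphenoid_outer",
        "sphenoid_inner",
    ]
    frame = lset.frame
    if frame == "world":
        required.append("midsagittal")
    lset.require(*required)

    if frame == "world":
        t = fit_acpc_transform(lset["AC"], lset["PC"], lset["midsagittal"])
        get = lambda name: apply_transform(t, lset[name])
    elif frame == "acpc":
        get = lambda name: lset[name]
    else:
        raise StatisticsError(
            f"subject {lset.subject_id!r} ({lset.side.value}): landmarks must be "
            f"in the world or acpc frame, got {frame!r}"
        )

    limen = get("limen_insulae")
    target = compute_target_point(get("hippocampal_sulcus"), get("innominate_sulcus"))
    angles = compute_approach_angles(
        ApproachVector(origin=limen, target=target, side=lset.side)
    )
    ridge = compute_sphenoid_angle(
        SphenoidRidgeLine(
            outer=get("sphenoid_outer"), inner=get("sphenoid_inner"), side=lset.side
        )
    )
    return {
        "subject_id": lset.subject_id,
        "side": lset.side.value,
        "theta_a": angles.theta_a,
        "theta_c": angles.theta_c,
        "sphenoid_angle": ridge,
        "limen_x": limen.x,
        "limen_y": limen.y,
        "limen_z": limen.z,
        "target_x": target.x,
        "target_y": target.y,
        "target_z": target.z,
    }


def build_cohort_table(sets: Iterable[LandmarkSet]) -> pd.DataFrame:
    """Measure every landmark set and assemble the per-trajectory table.

    World-frame sets are first AC-PC aligned from their own AC, PC and
    mid-sagittal landmarks; acpc-frame sets are measured directly.  The
    result has one row per (subject, side), ordered subject-then-side with
    right before left.
    """
    rows = [_measure_one(lset) for lset in sets]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    if df.duplicated(subset=["subject_id", "side"]).any():
        dup = df[df.duplicated(subset=["subject_id", "side"])].iloc[0]
        raise StatisticsError(
            f"duplicate cohort row for subject {dup['subject_id']!r} ({dup['side']})"
        )
    side_order = df["side"].map({"right": 0, "left": 1})
    df = (
        df.assign(_side_order=side_order)
        .sort_values(["subject_id", "_side_order"], kind="stable")
        .drop(columns="_side_order")
        .reset_index(drop=True)
    )
    return df


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise StatisticsError(f"cohort table missing columns: {sorted(missing)}")
    return df
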