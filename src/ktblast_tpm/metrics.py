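"""Comparison statistics between two acquisitions and cohort summaries.

Metrics between a pair of velocity curves (sequence 1 = the non-accelerated
reference, sequence 2 = the accelerated or repeated acquisition):

* PF (peak factor) = delta_v(seq2) / delta_v(seq1); ideally 1.
* nRMSD = RMS deviation between the dense curves divided by |delta_v| of
  the non-accelerated acquisition.
* c = Pearson correlation between the dense curves; ideally 1.
* Bland-Altman statistics of paired values (differences seq2 - seq1
  throughout): mean difference, sample sd (n-1), limits mean +/- 1.96 sd.
* Unpaired two-tailed pooled-variance t-test for group comparisons
  (p < 0.05 significant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import VelocityCurve, CurveFeatures, find_peaks

__all__ = [
    "ComparisonResult",
    "peak_factor",
    "nrmsd",
    "correlation",
    "bland_altman",
    "pooled_t_test",
    "compare_acquisitions",
    "results_to_frame",
    "summarize_cohort",
]


@dataclass
class ComparisonResult:
    """Per-direction comparison of one acquisition pair."""

    direction: str
    pf: float
    nrmsd: float
    corr: float
    dv_seq1: float
    dv_seq2: float
    dv_diff: float
    t_dias_seq1_ms: float
    t_dias_seq2_ms: float
    dt_dias_ms: float


def peak_factor(dv_seq1: float, dv_seq2: float) -> float:
    """Ratio of velocity differences delta_v(seq2) / delta_v(seq1)."""
    if dv_seq1 == 0:
        raise ZeroDivisionError("peak factor undefined: reference delta_v is zero")
    return dv_seq2 / dv_seq1


def nrmsd(u: np.ndarray, w: np.ndarray, dv_ref: float) -> float:
    """Root-mean-square deviation of the dense curves over |delta_v| reference."""
    u = np.asarray(u, float)
    w = np.asarray(w, float)
    if u.shape != w.shape:
        raise ValueError("curves must share the dense grid")
    if dv_ref == 0:
        raise ZeroDivisionError("nRMSD undefined: reference delta_v is zero")
    return float(np.sqrt(np.mean((u - w) ** 2)) / abs(dv_ref))


def correlation(u: np.ndarray, w: np.ndarray) -> float:
    """Pearson product-moment correlation of the dense curves (in [-1, 1])."""
    u = np.asarray(u, float)
    w = np.asarray(w, float)
    if u.shape != w.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("need two equal-length 1-D curves with n >= 2")
    if np.ptp(u) == 0 or np.ptp(w) == 0:
        raise ValueError("correlation undefined for a constant curve")
    return float(np.corrcoef(u, w)[0, 1])


def bland_altman(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, tuple[float, float]]:
    """Bland-Altman agreement of paired values.

    Differences are seq2 - seq1.  Returns (mean difference, sample sd with
    n-1 denominator, limits of agreement mean -/+ 1.96 sd).
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (seq1, seq2) pairs")
    d = arr[:, 1] - arr[:, 0]
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd)


def pooled_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-tailed equal-variance (pooled) t-test.

    Returns (t, p) with df = n_a + n_b - 2.  Degenerate input (zero pooled
    variance with equal means) yields t = 0, p = 1.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    with warnings.catch_warnings():
        # scipy warns about catastrophic cancellation for nearly identical
        # groups (the reproducibility arm routinely is); the pooled t is fine
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _common_dense(c1: VelocityCurve, c2: VelocityCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncate two dense curves to their common time window."""
    if c1.dense_v is None or c2.dense_v is None:
        raise ValueError("curves must be spline-resampled first")
    if c1.dt_ms != c2.dt_ms or c1.dense_t_ms[0] != c2.dense_t_ms[0]:
        raise ValueError("dense grids must share origin and step")
    n = min(len(c1.dense_v), len(c2.dense_v))
    return c1.dense_t_ms[:n], c1.dense_v[:n], c2.dense_v[:n]


def compare_acquisitions(
    seq1: Mapping[str, VelocityCurve],
    seq2: Mapping[str, VelocityCurve],
    systole_window: tuple[float, float] | None = None,
    diastole_window: tuple[float, float] | None = None,
) -> list[ComparisonResult]:
    """All pairwise metrics between two quantified acquisitions.

    ``seq1``/``seq2`` map direction -> dense `VelocityCurve` (seq1 is the
    non-accelerated reference).  Peak features are extracted on the common
    truncated window so both sequences use identical search windows.
    """
    out = []
    for direction in seq1:
        c1, c2 = seq1[direction], seq2[direction]
        t, u, w = _common_dense(c1, c2)
        dt = c1.dt_ms
        cc1 = VelocityCurve(direction, c1.t_ms, c1.v_cm_s, t, u, dt)
        cc2 = VelocityCurve(direction, c2.t_ms, c2.v_cm_s, t, w, dt)
        f1 = find_peaks(cc1, systole_window, diastole_window)
        f2 = find_peaks(cc2, systole_window, diastole_window)
        out.append(
            ComparisonResult(
                direction=direction,
                pf=peak_factor(f1.delta_v, f2.delta_v),
                nrmsd=nrmsd(u, w, f1.delta_v),
                corr=correlation(u, w),
                dv_seq1=f1.delta_v,
                dv_seq2=f2.delta_v,
                dv_diff=f2.delta_v - f1.delta_v,
                t_dias_seq1_ms=f1.t_dias_ms,
                t_dias_seq2_ms=f2.t_dias_ms,
                dt_dias_ms=f2.t_dias_ms - f1.t_dias_ms,
            )
        )
    return out


_MEAN_SD_METRICS = ("pf", "nrmsd", "corr")
_BA_METRICS = {"dv_diff": ("dv_seq1", "dv_seq2"), "dt_dias": ("t_dias_seq1_ms", "t_dias_seq2_ms")}


def results_to_frame(results: Mapping[str, Mapping[str, Sequence[ComparisonResult]]]) -> pd.DataFrame:
    """Flatten {arm_label: {subject: [ComparisonResult, ...]}} into a tidy frame."""
    rows = []
    for arm, per_subject in results.items():
        for subject, res_list in per_subject.items():
            for r in res_list:
                rows.append({"arm": arm, "subject": subject, **asdict(r)})
    return pd.DataFrame(rows)


def summarize_cohort(per_subject: pd.DataFrame, reference_arm: str = "no") -> dict[str, pd.DataFrame]:
    """Cohort tables: PF, nRMSD, c (mean, sd) and Bland-Altman of dv and t_dias.

    ``per_subject`` is a tidy frame with columns arm, subject, direction and
    the `ComparisonResult` fields; ``reference_arm`` labels the no-kt
    reproducibility comparisons.  Each table has one row per (arm,
    direction) with mean, sd and a pooled-t-test p-value versus the
    reference arm (p is NaN on the reference rows themselves).
    """
    tables: dict[str, pd.DataFrame] = {}
    arms = list(dict.fromkeys(per_subject["arm"]))
    directions = list(dict.fromkeys(per_subject["direction"]))

    def ref_values(metric: str, direction: str) -> np.ndarray:
        sel = (per_subject["arm"] == reference_arm) & (per_subject["direction"] == direction)
        return per_subject.loc[sel, metric].to_numpy()

    for metric in _MEAN_SD_METRICS:
        rows = []
        for arm in arms:
            for direction in directions:
                sel = (per_subject["arm"] == arm) & (per_subject["direction"] == direction)
                vals = per_subject.loc[sel, metric].to_numpy()
                ref = ref_values(metric, direction)
                if arm == reference_arm or len(vals) < 2 or len(ref) < 2:
                    p = np.nan
                else:
                    try:
                        _, p = pooled_t_test(ref, vals)
                    except ValueError:
                        p = np.nan
                rows.append(
                    {
                        "R": arm,
                        "metric": metric,
                        "direction": direction,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                        "p": p,
                    }
                )
        tables[metric] = pd.DataFrame(rows)

    for metric, (col1, col2) in _BA_METRICS.items():
        rows = []
        for arm in arms:
            for direction in directions:
                sel = (per_subject["arm"] == arm) & (per_subject["direction"] == direction)
                pairs = per_subject.loc[sel, [col1, col2]].to_numpy()
                if len(pairs) >= 2:
                    mean, sd, limits = bland_altman(pairs)
                else:
                    mean = float(pairs[0, 1] - pairs[0, 0]) if len(pairs) else np.nan
                    sd, limits = 0.0, (np.nan, np.nan)
                diffs = pairs[:, 1] - pairs[:, 0]
                ref_sel = (per_subject["arm"] == reference_arm) & (
                    per_subject["direction"] == direction
                )
                ref_pairs = per_subject.loc[ref_sel, [col1, col2]].to_numpy()
                ref_diffs = ref_pairs[:, 1] - ref_pairs[:, 0]
                if arm == reference_arm or len(diffs) < 2 or len(ref_diffs) < 2:
                    p = np.nan
                else:
                    try:
                        _, p = pooled_t_test(ref_diffs, diffs)
                    except ValueError:
                        p = np.nan
                rows.append(
                    {
                        "R": arm,
                        "metric": metric,
                        "direction": direction,
                        "mean": mean,
                        "sd": sd,
                        "lower_loa": limits[0],
                        "upper_loa": limits[1],
                        "p": p,
                    }
                )
        tables[metric] = pd.DataFrame(rows)
    return tables
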