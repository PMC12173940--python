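"""Binned spindle-vs-cell-volume scaling analysis and group statistics.

Implements the study's quantification conventions: cell-volume binning in
left-closed right-open 500 µm³ intervals, Welch's two-sided t-test with
Satterthwaite degrees of freedom, Cohen's d with (n-1)-weighted pooled
standard deviation, Spearman rank correlation with average ranks for ties,
per-bin percent median deficits (subscaling profiles), part-of-whole
occupancy percentages and fold changes against a control median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .records import CellRecord, Lineage

#: Default cell-volume bin edges (µm³): six 500-µm³ bins whose left edges
#: run from 1,000 through 3,500.
DEFAULT_BIN_EDGES = tuple(float(e) for e in range(1000, 4500, 500))

#: Bucket key for records outside the binned volume range.
UNBINNED = "unbinned"


@dataclass(frozen=True)
class BinSummary:
    """Median and interquartile range of one cell-volume bin."""

    bin_low: float
    bin_high: float
    n: int
    median: float
    iqr_low: float
    iqr_high: float

    def __post_init__(self):
        if self.bin_low >= self.bin_high:
            raise ValidationError("bin_low must be below bin_high")
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if self.n > 0 and not self.iqr_low <= self.median <= self.iqr_high:
            raise ValidationError("require iqr_low <= median <= iqr_high")


@dataclass(frozen=True)
class ComparisonResult:
    """Welch's t-test plus Cohen's d for two independent samples."""

    t_statistic: float
    df_welch: float
    p_two_sided: float
    cohens_d: float
    n_a: int
    n_b: int

    def __post_init__(self):
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValidationError("p must lie in [0, 1]")
        if self.df_welch <= 0:
            raise ValidationError("Welch df must be positive")


@dataclass(frozen=True)
class SubscalingProfile:
    """Per-bin percent median deficits of a test group against a reference.

    ``deficits`` is NaN for bins where either group is empty. ``flagged``
    marks bins whose count in either group is below the reporting minimum;
    those bins are excluded from ``max_deficit``.
    """

    bin_lows: tuple[float, ...]
    bin_highs: tuple[float, ...]
    deficits_percent: tuple[float, ...]
    flagged: tuple[bool, ...]
    max_deficit_percent: float


def bin_by_cell_volume(
    records: Sequence[CellRecord],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict[Hashable, list[CellRecord]]:
    """Partition records into left-closed right-open cell-volume bins.

    Records with ``V_cell`` outside ``[edges[0], edges[-1])`` land in the
    explicit :data:`UNBINNED` bucket — nothing is dropped silently. Bin keys
    are ``(low, high)`` tuples.
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2:
        raise ValidationError("need at least 2 bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")

    buckets: dict[Hashable, list[CellRecord]] = {
        (float(lo), float(hi)): [] for lo, hi in zip(edges[:-1], edges[1:])
    }
    buckets[UNBINNED] = []
    keys = list(buckets)
    for rec in records:
        idx = np.searchsorted(edges, rec.V_cell, side="right") - 1
        if 0 <= idx < len(edges) - 1:
            buckets[keys[idx]].append(rec)
        else:
            buckets[UNBINNED].append(rec)
    return buckets


def summarize_bins(
    binned: Mapping[Hashable, Sequence[CellRecord]],
    value: str = "V_spindle",
) -> list[BinSummary]:
    """Median/IQR summaries of a record attribute per volume bin,
    in ascending bin order (the unbinned bucket is not summarized)."""
    summaries = []
    for key in sorted(k for k in binned if k != UNBINNED):
        lo, hi = key
        vals = np.array([getattr(r, value) for r in binned[key]], dtype=float)
        if len(vals) == 0:
            summaries.append(BinSummary(lo, hi, 0, np.nan, np.nan, np.nan))
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        summaries.append(BinSummary(lo, hi, len(vals), float(med),
                                    float(q25), float(q75)))
    return summaries


def compare_groups(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Welch's two-sided t-test and Cohen's d for two independent samples.

    Cohen's d uses the (n-1)-weighted pooled standard deviation,
    ``d = (mean_a - mean_b) / s_pooled``. Degenerate inputs: two samples with
    zero variance and equal means give ``t=0, p=1, d=0``; zero pooled
    variance with unequal means raises :class:`DegenerateDataError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    pooled_var = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        if ma == mb:
            return ComparisonResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0,
                                    len(a), len(b))
        raise DegenerateDataError(
            "zero pooled variance with unequal means: effect size undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    d = (ma - mb) / np.sqrt(pooled_var)
    return ComparisonResult(
        t_statistic=float(res.statistic),
        df_welch=float(res.df),
        p_two_sided=float(res.pvalue),
        cohens_d=float(d),
        n_a=len(a),
        n_b=len(b),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises :class:`DegenerateDataError` for a constant input vector, where
    the rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def subscaling_profile(
    bins_ref: Sequence[BinSummary],
    bins_test: Sequence[BinSummary],
    min_n: int = 5,
) -> SubscalingProfile:
    """Percent median deficit of the test group per matched volume bin.

    ``deficit_b = 100 * (median_ref - median_test) / median_ref``. Bins where
    either group has fewer than ``min_n`` records are flagged and excluded
    from the maximum. A zero reference median raises
    :class:`DegenerateDataError`.
    """
    if len(bins_ref) != len(bins_test):
        raise ValidationError("bin summary lists must have equal length")
    lows, highs, deficits, flagged = [], [], [], []
    for ref, test in zip(bins_ref, bins_test):
        if (ref.bin_low, ref.bin_high) != (test.bin_low, test.bin_high):
            raise ValidationError("bin edges of reference and test must match")
        lows.append(ref.bin_low)
        highs.append(ref.bin_high)
        if ref.n == 0 or test.n == 0:
            deficits.append(np.nan)
            flagged.append(True)
            continue
        if ref.median == 0:
            raise DegenerateDataError(
                f"zero reference median in bin [{ref.bin_low}, {ref.bin_high})"
            )
        deficits.append(100.0 * (ref.median - test.median) / ref.median)
        flagged.append(ref.n < min_n or test.n < min_n)
    usable = [d for d, f in zip(deficits, flagged) if not f]
    if not usable:
        raise DegenerateDataError("no bin meets the minimum count for reporting")
    return SubscalingProfile(
        bin_lows=tuple(lows),
        bin_highs=tuple(highs),
        deficits_percent=tuple(deficits),
        flagged=tuple(flagged),
        max_deficit_percent=float(max(usable)),
    )


def occupancy(part_volume: float, whole_volume: float) -> float:
    """Percent of a whole volume occupied by a part (e.g. centrosome:cell)."""
    if whole_volume <= 0:
        raise ValidationError("whole_volume must be positive")
    if part_volume < 0:
        raise ValidationError("part_volume must be >= 0")
    if part_volume > whole_volume:
        raise ValidationError(
            f"inconsistent record: part ({part_volume:.3g}) exceeds whole "
            f"({whole_volume:.3g})"
        )
    return 100.0 * part_volume / whole_volume


@dataclass(frozen=True)
class FoldChangeResult:
    """Values normalized to a control median, with summary statistics."""

    normalized: tuple[float, ...]
    median_fold: float
    iqr_low: float
    iqr_high: float
    control_median: float


def fold_change_vs_control(
    values: Sequence[float],
    control_values: Sequence[float],
) -> FoldChangeResult:
    """Normalize values to the control median; report the median fold.

    Raises :class:`DegenerateDataError` when the control median is zero.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(control) == 0 or len(values) == 0:
        raise ValidationError("values and control must be non-empty")
    ctrl_med = float(np.median(control))
    if ctrl_med == 0:
        raise DegenerateDataError("zero control median: fold change undefined")
    normalized = values / ctrl_med
    q25, med, q75 = np.percentile(normalized, [25, 50, 75])
    return FoldChangeResult(
        normalized=tuple(float(v) for v in normalized),
        median_fold=float(med),
        iqr_low=float(q25),
        iqr_high=float(q75),
        control_median=ctrl_med,
    )


def intermitotic_times(lineage: Lineage) -> np.ndarray:
    """Cell-cycle durations: successive differences of division times.

    A lineage with fewer than 2 division events yields an empty array
    (a short recording, not an error).
    """
    t = lineage.division_times
    if len(t) < 2:
        return np.empty(0)
    return np.diff(t)
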