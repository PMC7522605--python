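"""Replica-level aggregation: equilibration discard, distribution summaries,
and the between-system significance comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.signal import find_peaks


class StatsError(Exception):
    pass


@dataclass
class MetricSeries:
    """One metric's per-frame values for one replica of one system."""

    system_label: str
    replica_label: str
    metric_name: str
    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")


@dataclass
class DistributionSummary:
    """Histogram + KDE descriptor of pooled metric values."""

    counts: np.ndarray
    bin_edges: np.ndarray
    grid: np.ndarray | None
    density: np.ndarray | None
    n_modes: int
    degenerate: bool = False


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")
        if self.p_value < 0.01:
            self.stars = "**"
        elif self.p_value < 0.05:
            self.stars = "*"
        else:
            self.stars = ""


def discard_equilibration(series: MetricSeries, fraction: float = 0.2) -> MetricSeries:
    """Drop the first ``ceil(fraction * n)`` points (equilibration burn-in)."""
    if not (0.0 <= fraction < 1.0):
        raise StatsError("fraction must be in [0, 1)")
    n = len(series.values)
    start = math.ceil(fraction * n)
    return replace(series, values=series.values[start:], times=series.times[start:])


def distribution_summary(
    values: np.ndarray,
    n_bins: int = 50,
    grid_size: int = 512,
    prominence_fraction: float = 0.05,
) -> DistributionSummary:
    """Histogram and Silverman-bandwidth KDE with a mode count.

    Modes are density maxima whose prominence exceeds
    ``prominence_fraction`` of the peak density.  Constant input yields a
    degenerate summary without a KDE.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 2:
        raise StatsError("distribution_summary needs at least 2 values")
    counts, edges = np.histogram(values, bins=n_bins)
    if np.ptp(values) < 1e-12:
        return DistributionSummary(counts, edges, None, None, n_modes=0, degenerate=True)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    pad = 3.0 * values.std()
    grid = np.linspace(values.min() - pad, values.max() + pad, grid_size)
    density = kde(grid)
    # normalize on the evaluation grid so the discrete integral is exactly 1
    density = density / np.trapezoid(density, grid)
    peaks, _ = find_peaks(density, prominence=prominence_fraction * density.max())
    return DistributionSummary(counts, edges, grid, density, n_modes=int(len(peaks)))


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Welch two-sided t-test on per-replica means.

    The unit of replication is the replica (typically n = 3 per system),
    not the frame, to avoid frame autocorrelation inflating significance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise StatsError("compare_groups needs at least 2 replicas per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return ComparisonResult(label_a, label_b, 0.0, 1.0)
        raise StatsError("both groups constant with different means: t undefined")
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(label_a, label_b, float(t_stat), float(p))
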