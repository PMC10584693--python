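"""Cell-size scaling statistics.

Presentation-layer statistics for copy-number and imaging results: binned
means with standard errors against cell volume, ordinary least-squares
lines through replicate means, the concentration ratio expected for a
species kept at constant amount, copies-per-nucleoid matching, and
flow-cytometry background subtraction with a two-day error envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinnedSeries",
    "LinearFit",
    "binned_means",
    "default_edges",
    "fit_linear",
    "constant_amount_ratio",
    "mtdna_per_nucleoid",
    "flow_background_subtract",
    "compare_strains",
]


@dataclass(frozen=True)
class BinnedSeries:
    """Binned means at bin centers with s.e. (= s.d./sqrt(count)) per bin."""

    centers: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"center": self.centers, "mean": self.means,
             "sem": self.sems, "count": self.counts}
        )


@dataclass(frozen=True)
class LinearFit:
    """OLS slope/intercept with standard errors."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float


def default_edges(x: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Equal-width bin edges spanning the 1st-99th percentile of x."""
    lo, hi = np.percentile(np.asarray(x, dtype=float), [1, 99])
    if lo == hi:
        raise ValueError("degenerate data range for binning")
    return np.linspace(lo, hi, n_bins + 1)


def binned_means(
    x: np.ndarray,
    y: np.ndarray,
    edges: np.ndarray,
    min_count: int = 5,
) -> BinnedSeries:
    """Mean and s.e. of y in bins of x; bins with < min_count points dropped.

    Single-point bins passing min_count report s.e. 0 (undefined sample
    s.d.).  Bin centers are the midpoints of the edges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly ascending")
    centers, means, sems, counts = [], [], [], []
    for lo, hi, is_last in zip(edges[:-1], edges[1:],
                               [False] * (len(edges) - 2) + [True]):
        sel = (x >= lo) & ((x <= hi) if is_last else (x < hi))
        n = int(sel.sum())
        if n < max(min_count, 1):
            continue
        yy = y[sel]
        centers.append(0.5 * (lo + hi))
        means.append(float(yy.mean()))
        sems.append(float(yy.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
        counts.append(n)
    if not centers:
        raise ValueError("no bin reaches min_count")
    return BinnedSeries(np.array(centers), np.array(means),
                        np.array(sems), np.array(counts))


def fit_linear(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS line through (x, y) — typically the means of biological replicates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct x values")
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return LinearFit(float(slope), float(y[0] - slope * x[0]),
                         float("nan"), float("nan"))
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.stderr), float(res.intercept_stderr))


def constant_amount_ratio(v_small: float, v_big: float) -> float:
    """Big-to-small concentration ratio for a species of constant amount.

    A transcript whose copy number does not change with volume is diluted:
    its concentration in big cells relative to small cells is v_small/v_big.
    """
    if v_small <= 0 or v_big <= 0:
        raise ValueError("volumes must be > 0")
    return v_small / v_big


def mtdna_per_nucleoid(
    volumes_copies: np.ndarray,
    copies_per_cell: np.ndarray,
    volumes_nucleoids: np.ndarray,
    nucleoids_per_cell: np.ndarray,
    edges: np.ndarray,
    min_count: int = 5,
) -> pd.DataFrame:
    """Per-volume-bin ratio of mtDNA copies to nucleoid count.

    The two measurements come from different experiments (qPCR populations
    vs imaged cells), so they are matched on common volume bins.  Bins where
    the nucleoid mean is zero report NaN.
    """
    copies = binned_means(volumes_copies, copies_per_cell, edges, min_count)
    nucs = binned_means(volumes_nucleoids, nucleoids_per_cell, edges, min_count)
    common = np.intersect1d(copies.centers, nucs.centers)
    if common.size == 0:
        raise ValueError("no overlapping volume bins")
    ci = np.searchsorted(copies.centers, common)
    ni = np.searchsorted(nucs.centers, common)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nucs.means[ni] > 0, copies.means[ci] / nucs.means[ni], np.nan)
    return pd.DataFrame(
        {"center": common, "copies_per_cell": copies.means[ci],
         "nucleoids_per_cell": nucs.means[ni], "copies_per_nucleoid": ratio}
    )


def flow_background_subtract(
    sample_days: list[BinnedSeries],
    control_days: list[BinnedSeries],
) -> pd.DataFrame:
    """Autofluorescence-corrected flow-cytometry signal per scatter bin.

    For each day, the control (non-fluorescent strain) bin mean is
    subtracted from the sample bin mean at identical bin edges.  With two
    day-replicates the point estimate is the day mean; the error envelope
    runs from min(day signals) - that day's s.e. to max(day signals) + that
    day's s.e.
    """
    if len(sample_days) != len(control_days) or not sample_days:
        raise ValueError("need equally many sample and control day series")
    base = sample_days[0].centers
    for s in list(sample_days) + list(control_days):
        if s.centers.shape != base.shape or not np.allclose(s.centers, base):
            raise ValueError("bin centers differ between series")
    corrected = np.stack(
        [s.means - c.means for s, c in zip(sample_days, control_days)]
    )
    sems = np.stack([s.sems for s in sample_days])
    hi_day = np.argmax(corrected, axis=0)
    lo_day = np.argmin(corrected, axis=0)
    cols = np.arange(base.size)
    return pd.DataFrame(
        {
            "center": base,
            "signal": corrected.mean(axis=0),
            "envelope_low": corrected[lo_day, cols] - sems[lo_day, cols],
            "envelope_high": corrected[hi_day, cols] + sems[hi_day, cols],
        }
    )


def compare_strains(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-tailed two-sample t-test between replicate-level values.

    Also reports Shapiro-Wilk normality p-values for each group (reported,
    not enforced).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a, b)
    out = {"t": float(t), "p": float(p)}
    for name, grp in (("shapiro_p_a", a), ("shapiro_p_b", b)):
        out[name] = float(stats.shapiro(grp).pvalue) if grp.size >= 3 else float("nan")
    return out
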