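"""Frequency distributions and two-sample comparison of spine dimensions.

Histograms use the √N rule for the bin count (nearest integer to the square
root of the number of observations, halves rounded away from zero), equal
width bins spanning the observed [min, max]. Relative frequencies divide the
counts by N, and the ogive is their running (cumulative) sum.

The two-sample Kolmogorov–Smirnov statistic D = sup|ECDF_x − ECDF_y| is
computed on the raw samples, never on binned ogives, so it does not depend
on the bin rule; the two-sided p-value uses the asymptotic Kolmogorov
distribution with effective size n = n_x·n_y/(n_x + n_y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import Dataset


def sqrt_bins(n_observations: int) -> int:
    """Number of histogram bins by the √N rule (half rounded away from zero)."""
    if n_observations < 1:
        raise ValueError("need at least one observation")
    return int(math.floor(math.sqrt(n_observations) + 0.5))


@dataclass
class HistogramSpec:
    """An √N-binned frequency distribution of one measurement."""

    n_observations: int
    n_bins: int
    bin_edges: np.ndarray          # length n_bins + 1, μm
    counts: np.ndarray             # integer counts per bin
    relative_frequency: np.ndarray  # counts / N, sums to 1
    cumulative_probability: np.ndarray  # running sum, last value 1
    degenerate: bool = False       # all observations identical → single bin


def histogram(values) -> HistogramSpec:
    """Build the √N-binned histogram of a sample of measurements."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("histogram input must be finite")
    n = int(v.size)
    if np.min(v) == np.max(v):
        counts = np.array([n])
        edges = np.array([v[0], v[0]])
        rel = counts / n
        return HistogramSpec(n, 1, edges, counts, rel, np.cumsum(rel), degenerate=True)
    k = sqrt_bins(n)
    counts, edges = np.histogram(v, bins=k, range=(float(np.min(v)), float(np.max(v))))
    rel = counts / n
    return HistogramSpec(n, k, edges, counts, rel, np.cumsum(rel))


def ogive(hist: HistogramSpec) -> np.ndarray:
    """Cumulative-probability curve of a histogram (prefix sums of rel. freq.)."""
    return np.cumsum(hist.relative_frequency)


@dataclass
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    statistic: float
    p_value: float
    n_x: int
    n_y: int


def ks_two_sample(x, y) -> KSResult:
    """Two-sided two-sample KS test on raw samples (asymptotic p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    d = float(stats.ks_2samp(x, y, alternative="two-sided", method="asymp").statistic)
    en = x.size * y.size / (x.size + y.size)
    p = float(np.clip(special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))
    return KSResult(statistic=d, p_value=p, n_x=int(x.size), n_y=int(y.size))


def compare_distributions(
    dataset: Dataset,
    metric: str,
    region: str,
    compartment: str = "all",
) -> pd.DataFrame:
    """KS comparison of a spine dimension between the two strains of a dataset.

    Parameters
    ----------
    metric : ``"length"`` or ``"width"``.
    compartment : ``"all"``, ``"apical"`` or ``"basal"``.

    Returns a one-row table with D, p and the two sample sizes, plus the √N
    bin counts used for each strain's plotted histogram.
    """
    col = {"length": "length_um", "width": "width_um"}[metric]
    sub = dataset.subset(region=region)
    if compartment != "all":
        sub = sub.subset(compartment=compartment)
    strains = sorted(sub.spines["strain"].unique())
    if len(strains) != 2:
        raise ValueError(f"expected exactly 2 strains, found {strains}")
    x = sub.spines.loc[sub.spines["strain"] == strains[0], col].to_numpy()
    y = sub.spines.loc[sub.spines["strain"] == strains[1], col].to_numpy()
    res = ks_two_sample(x, y)
    return pd.DataFrame(
        [
            {
                "metric": metric,
                "region": region,
                "compartment": compartment,
                "strain_x": strains[0],
                "strain_y": strains[1],
                "n_x": res.n_x,
                "n_y": res.n_y,
                "bins_x": sqrt_bins(res.n_x),
                "bins_y": sqrt_bins(res.n_y),
                "ks_statistic": res.statistic,
                "p_value": res.p_value,
            }
        ]
    )
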