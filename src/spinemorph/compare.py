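"""Strain-level comparison of per-neuron quantities.

The analysis unit is the neuron: every metric is first reduced to one value
per neuron (spine density per 25 μm, per-class spine counts, per-cluster
counts, soma metrics), then the two strains are compared with the classic
pooled-variance unpaired two-tailed Student's t-test and Holm–Bonferroni
step-down correction within the declared metric family. Significance is
judged at α = 0.05 on the adjusted p-values. A mouse-level aggregation is
available so users can probe pseudoreplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import class_frequencies, classify_spines
from .datamodel import Dataset

NEURON_KEYS = ["strain", "mouse_id", "region", "neuron_id"]
SUMMARY_COLUMNS = NEURON_KEYS + ["compartment", "metric", "value"]

#: Reference length for reporting spine density (spines per 25 μm).
DENSITY_WINDOW_UM = 25.0


def _emit(df: pd.DataFrame, metric: str, compartment: str, value_col: str) -> pd.DataFrame:
    out = df[NEURON_KEYS].copy()
    out["compartment"] = compartment
    out["metric"] = metric
    out["value"] = df[value_col].to_numpy()
    return out


def neuron_density(dataset: Dataset, segment_length_um: float = DENSITY_WINDOW_UM) -> pd.DataFrame:
    """Per-neuron spine density (spines per 25 μm) from the density segments.

    Only segments of *segment_length_um* (default 25 μm, the counting
    window) enter the density estimate, so the shorter morphology segments
    of a combined table do not dilute it; if no segment matches, all
    segments are used with a warning. Each segment contributes
    ``spine_count / segment_length × 25``; a neuron's value is the mean
    over its segments, emitted for all dendrites and separately for the
    apical and basal compartments.
    """
    seg = dataset.segments.copy()
    if not len(seg):
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    matching = seg[seg["segment_length_um"] == segment_length_um]
    if len(matching):
        seg = matching.copy()
    else:
        warnings.warn(
            f"no segments of length {segment_length_um} μm; "
            "using all segments for density"
        )
    seg["density"] = seg["spine_count"] / seg["segment_length_um"] * DENSITY_WINDOW_UM
    frames = []
    for compartment in ("all", "apical", "basal"):
        sub = seg if compartment == "all" else seg[seg["compartment"] == compartment]
        if not len(sub):
            warnings.warn(f"no segments for compartment {compartment!r}; density skipped")
            continue
        per = sub.groupby(NEURON_KEYS, observed=True)["density"].mean().reset_index()
        frames.append(_emit(per, "density_per_25um", compartment, "density"))
    return pd.concat(frames, ignore_index=True)


def neuron_class_counts(dataset: Dataset, scheme: str) -> pd.DataFrame:
    """Per-neuron spine counts in each shape class of a scheme."""
    classified = classify_spines(dataset, scheme)
    if not len(classified):
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    if scheme == "binary":
        classified["shape_class"] = classified["length_class"] + "|" + classified["head_class"]
    else:
        classified["shape_class"] = classified["risher_class"]
    return _per_neuron_category_counts(classified, "shape_class", prefix=scheme)


def neuron_cluster_counts(clustered_spines: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron spine counts per cluster label (small/long/wide).

    Input is the labelled spine table from
    :func:`spinemorph.clustering.cluster_spines` (k = 3).
    """
    if "cluster_label" not in clustered_spines.columns:
        raise ValueError("expected a 'cluster_label' column (k = 3 clustering)")
    return _per_neuron_category_counts(clustered_spines, "cluster_label", prefix="cluster")


def _per_neuron_category_counts(df: pd.DataFrame, col: str, prefix: str) -> pd.DataFrame:
    categories = sorted(df[col].unique())
    frames = []
    for compartment in ("all", "apical", "basal"):
        sub = df if compartment == "all" else df[df["compartment"] == compartment]
        if not len(sub):
            continue
        neurons = sub[NEURON_KEYS].drop_duplicates()
        counts = (
            sub.groupby(NEURON_KEYS + [col], observed=True).size().rename("value").reset_index()
        )
        for cat in categories:
            c = counts[counts[col] == cat][NEURON_KEYS + ["value"]]
            merged = neurons.merge(c, on=NEURON_KEYS, how="left").fillna({"value": 0})
            frames.append(_emit(merged, f"{prefix}:{cat}", compartment, "value"))
    return pd.concat(frames, ignore_index=True)


def neuron_soma(dataset: Dataset) -> pd.DataFrame:
    """Per-neuron soma perimeter, area and circularity."""
    from .soma import soma_metrics

    m = soma_metrics(dataset)
    if not len(m):
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    frames = [
        _emit(m, name, "all", col)
        for name, col in (
            ("soma_perimeter_um", "perimeter_um"),
            ("soma_area_um2", "area_um2"),
            ("soma_circularity", "circularity"),
        )
    ]
    return pd.concat(frames, ignore_index=True)


def summarize_neurons(dataset: Dataset, metric: str, **kwargs) -> pd.DataFrame:
    """Dispatch to one of the per-neuron summaries.

    ``metric`` ∈ {"density", "binary", "risher", "soma"}; cluster counts
    need a labelled spine table and are produced by
    :func:`neuron_cluster_counts` directly.
    """
    if metric == "density":
        return neuron_density(dataset)
    if metric in ("binary", "risher"):
        return neuron_class_counts(dataset, metric)
    if metric == "soma":
        return neuron_soma(dataset)
    raise ValueError(f"unknown metric {metric!r}")


def aggregate_to_mice(summaries: pd.DataFrame) -> pd.DataFrame:
    """Collapse neuron-level summaries to mouse means (pseudoreplication probe)."""
    g = summaries.groupby(
        ["strain", "mouse_id", "region", "compartment", "metric"], observed=True
    )["value"].mean().reset_index()
    g["neuron_id"] = "mouse_mean"
    return g[SUMMARY_COLUMNS]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    flagged: bool = False  # zero pooled variance with equal means


def student_t(x, y) -> TTestResult:
    """Classic pooled-variance unpaired two-tailed Student's t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = int(x.size + y.size - 2)
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=df, p=1.0, flagged=True)
        raise ValueError("zero pooled variance with unequal means: t is degenerate")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm–Bonferroni step-down adjustment.

    Returns (adjusted p-values, reject decisions at *alpha*) in the original
    order. Adjusted p-values are the running maxima of min(1, (m−i+1)·p_(i))
    over the ascending order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def compare_strains(
    summaries: pd.DataFrame,
    metrics: list[str] | None = None,
    region: str | None = None,
    compartment: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare the two strains on a family of per-neuron metrics.

    The rows of *summaries* matching *region*/*compartment* and the metric
    family are tested one metric at a time (Student's t on neuron values),
    and the family's p-values are Holm-adjusted together. The family should
    mirror one figure panel: the set of simultaneous shape or cluster
    categories within one region × compartment.
    """
    sub = summaries[summaries["compartment"] == compartment]
    if region is not None:
        sub = sub[sub["region"] == region]
    strains = sorted(sub["strain"].unique())
    if len(strains) != 2:
        raise ValueError(f"expected exactly 2 strains, found {strains}")
    if metrics is None:
        metrics = sorted(sub["metric"].unique())

    rows = []
    for metric in metrics:
        m = sub[sub["metric"] == metric]
        x = m.loc[m["strain"] == strains[0], "value"].to_numpy()
        y = m.loc[m["strain"] == strains[1], "value"].to_numpy()
        if x.size < 2 or y.size < 2:
            warnings.warn(f"metric {metric!r} missing in one strain; skipped")
            continue
        res = student_t(x, y)
        rows.append(
            {
                "metric": metric,
                "region": region if region is not None else "all",
                "compartment": compartment,
                f"mean_{strains[0]}": x.mean(),
                f"sd_{strains[0]}": x.std(ddof=1),
                f"n_{strains[0]}": x.size,
                f"mean_{strains[1]}": y.mean(),
                f"sd_{strains[1]}": y.std(ddof=1),
                f"n_{strains[1]}": y.size,
                "t": res.t,
                "df": res.df,
                "p_raw": res.p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        p_adj, reject = holm_bonferroni(out["p_raw"].to_numpy(), alpha=alpha)
        out["p_adj"] = p_adj
        out["significant"] = reject
    return out
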