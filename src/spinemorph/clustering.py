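"""K-means clustering of spines on (width, length) with automatic k-selection.

Features are z-scored per axis (sample standard deviation, n−1 denominator)
before clustering so the two dimensions contribute comparably. K-means is
fitted with k-means++ seeding and multiple restarts, keeping the solution
with the lowest within-cluster sum of squares (WSS); the cluster count is
selected as the argmax of the mean silhouette over a candidate range, with
the WSS curve reported alongside for elbow inspection. For k = 3 the
clusters are named from their raw-μm centroids: *long* has the greatest
mean length, *wide* the greatest mean width among the remaining two, and
*small* is the third.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datamodel import Dataset

FEATURE_NAMES = ("width_um", "length_um")
#: Silhouette is O(n²); larger fits score a fixed-seed subsample of this size.
SILHOUETTE_MAX_N = 5000


@dataclass
class ScaledFeatures:
    """Z-scored (width, length) feature matrix with its scaling parameters."""

    raw: np.ndarray       # (n, 2) in μm, columns (width, length)
    scaled: np.ndarray    # (n, 2) dimensionless
    mean: np.ndarray      # per-feature mean (μm)
    sd: np.ndarray        # per-feature sample SD (μm, n−1 denominator)

    def unscale(self, points: np.ndarray) -> np.ndarray:
        """Map scaled coordinates back to raw μm."""
        return np.asarray(points, dtype=float) * self.sd + self.mean


def zscale(raw) -> ScaledFeatures:
    """Centre and scale each feature to zero mean and unit sample SD."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (width, length) pairs")
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 points to scale")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    for i, name in enumerate(FEATURE_NAMES):
        if sd[i] == 0:
            raise ValueError(f"feature {name} has zero variance; cannot z-scale")
    return ScaledFeatures(raw=raw, scaled=(raw - mean) / sd, mean=mean, sd=sd)


@dataclass
class ClusterModel:
    """A fitted k-means solution in scaled and raw units."""

    k: int
    centroids_scaled: np.ndarray   # (k, 2)
    centroids_raw: np.ndarray      # (k, 2) in μm, columns (width, length)
    assignments: np.ndarray        # cluster index per spine
    wss: float                     # within-cluster sum of squared distances
    silhouette_mean: float
    labels: dict[int, str] | None = field(default=None)  # k = 3 only

    def label_of(self, assignment: np.ndarray) -> np.ndarray:
        if self.labels is None:
            raise ValueError("cluster labels are only defined for k = 3 fits")
        return np.vectorize(self.labels.get)(assignment)


def _mean_silhouette(scaled: np.ndarray, assignments: np.ndarray, seed: int) -> float:
    n = scaled.shape[0]
    n_labels = len(np.unique(assignments))
    if n_labels < 2 or n_labels >= n:  # silhouette undefined
        return float("nan")
    if n > SILHOUETTE_MAX_N:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, SILHOUETTE_MAX_N, replace=False)
        sub, lab = scaled[idx], assignments[idx]
        if len(np.unique(lab)) < 2:
            return float("nan")
        return float(silhouette_score(sub, lab))
    return float(silhouette_score(scaled, assignments))


def kmeans_fit(
    features: ScaledFeatures,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    compute_silhouette: bool = True,
) -> ClusterModel:
    """Fit k-means on the scaled features, best of *n_restarts* by WSS.

    Deterministic given (features, k, seed, n_restarts). For k = 3 the
    small/long/wide labelling is attached. ``compute_silhouette=False``
    skips the O(n²) silhouette (reported as NaN) for bulk simulation work.
    """
    n = features.scaled.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    assignments = km.fit_predict(features.scaled)
    centroids_raw = features.unscale(km.cluster_centers_)
    model = ClusterModel(
        k=k,
        centroids_scaled=km.cluster_centers_.copy(),
        centroids_raw=centroids_raw,
        assignments=assignments,
        wss=float(km.inertia_),
        silhouette_mean=(
            _mean_silhouette(features.scaled, assignments, seed)
            if compute_silhouette
            else float("nan")
        ),
    )
    if k == 3:
        model.labels = label_clusters(centroids_raw)
    return model


@dataclass
class KSelection:
    """Diagnostics of silhouette/WSS cluster-count selection."""

    best_k: int
    k_values: list[int]
    silhouette: list[float]
    wss: list[float]


def select_k(
    features: ScaledFeatures,
    k_range: range = range(2, 9),
    seed: int = 0,
    n_restarts: int = 10,
) -> KSelection:
    """Select the cluster count as the silhouette argmax over *k_range*.

    The WSS curve is returned for elbow inspection. Candidate k must satisfy
    2 ≤ k ≤ n − 1.
    """
    n = features.scaled.shape[0]
    ks = [k for k in k_range]
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if np.allclose(features.scaled, features.scaled[0]):
        raise ValueError("all points identical; cluster-count selection undefined")
    sil, wss = [], []
    for k in ks:
        m = kmeans_fit(features, k, seed=seed, n_restarts=n_restarts)
        sil.append(m.silhouette_mean)
        wss.append(m.wss)
    best = ks[int(np.nanargmax(sil))]
    return KSelection(best_k=best, k_values=ks, silhouette=sil, wss=wss)


def label_clusters(centroids_raw) -> dict[int, str]:
    """Name three raw-μm centroids small / long / wide.

    *long* is the centroid with maximal mean length; of the remaining two,
    *wide* has the maximal mean width and *small* is the other. Ties in a
    deciding coordinate raise, demanding manual labelling.
    """
    c = np.asarray(centroids_raw, dtype=float)
    if c.shape != (3, 2):
        raise ValueError("labelling is defined for exactly 3 (width, length) centroids")
    lengths = c[:, 1]
    order = np.argsort(lengths)
    if lengths[order[2]] == lengths[order[1]]:
        raise ValueError("tie in centroid length; label clusters manually")
    long_i = int(order[2])
    rest = [i for i in range(3) if i != long_i]
    widths = c[rest, 0]
    if widths[0] == widths[1]:
        raise ValueError("tie in centroid width; label clusters manually")
    wide_i = rest[int(np.argmax(widths))]
    small_i = next(i for i in rest if i != wide_i)
    return {small_i: "small", long_i: "long", wide_i: "wide"}


def cluster_spines(
    dataset: Dataset,
    region: str,
    k: int | str = 3,
    seed: int = 0,
    n_restarts: int = 10,
    k_range: range = range(2, 9),
    compute_silhouette: bool = True,
) -> tuple[ClusterModel, pd.DataFrame, KSelection | None]:
    """Cluster all spines of one region (both strains jointly).

    ``k="auto"`` first runs silhouette selection over *k_range*. Returns the
    fitted model, the spine table with ``cluster`` (and ``cluster_label`` for
    k = 3) columns, and the selection diagnostics when auto-selected.
    """
    sub = dataset.subset(region=region)
    spines = sub.spines.copy()
    if len(spines) < 3:
        raise ValueError(f"too few spines in region {region!r} to cluster")
    features = zscale(spines[["width_um", "length_um"]].to_numpy())
    selection = None
    if k == "auto":
        selection = select_k(features, k_range=k_range, seed=seed, n_restarts=n_restarts)
        k = selection.best_k
    model = kmeans_fit(
        features, int(k), seed=seed, n_restarts=n_restarts,
        compute_silhouette=compute_silhouette,
    )
    spines["cluster"] = model.assignments
    if model.labels is not None:
        spines["cluster_label"] = model.label_of(model.assignments)
    return model, spines, selection
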