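"""Z-scaling, k-means fitting, k-selection and small/long/wide labelling."""

import itertools

import numpy as np
import pytest

from spinemorph.clustering import (
    kmeans_fit,
    label_clusters,
    select_k,
    zscale,
)
from spinemorph.synthetic import default_region_config, sample_spine_dimensions


def test_zscale_symmetry_two_points():
    f = zscale(np.array([[0.0, 0.0], [2.0, 2.0]]))
    a = 1 / np.sqrt(2)
    np.testing.assert_allclose(f.scaled, [[-a, -a], [a, a]], atol=1e-12)
    np.testing.assert_allclose(f.scaled.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(f.scaled.std(axis=0, ddof=1), 1, atol=1e-9)


def test_zscale_inverse_round_trip(rng):
    raw = rng.uniform(0.1, 3.0, size=(500, 2))
    f = zscale(raw)
    np.testing.assert_allclose(f.unscale(f.scaled), raw, atol=1e-9)
    # moment oracle
    np.testing.assert_allclose(f.mean, raw.sum(axis=0) / 500, atol=1e-12)
    np.testing.assert_allclose(
        f.sd, np.sqrt(((raw - raw.mean(0)) ** 2).sum(axis=0) / 499), atol=1e-12
    )


def test_zscale_zero_variance_names_feature():
    pts = np.array([[1.0, 0.5], [1.0, 0.7], [1.0, 0.9]])
    with pytest.raises(ValueError, match="width_um"):
        zscale(pts)


def test_kmeans_three_points_three_clusters_zero_wss():
    f = zscale(np.array([[0.0, 0.0], [1.0, 5.0], [5.0, 1.0]]))
    model = kmeans_fit(f, k=3, seed=0)
    assert model.wss == pytest.approx(0.0, abs=1e-12)
    assert len(set(model.assignments)) == 3


def _min_wss_two_coloring(points: np.ndarray) -> float:
    best = np.inf
    n = len(points)
    for mask in itertools.product([0, 1], repeat=n):
        mask = np.array(mask, dtype=bool)
        if mask.all() or (~mask).all():
            continue
        wss = 0.0
        for grp in (points[mask], points[~mask]):
            wss += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


def test_kmeans_two_triads_matches_exhaustive_partition_oracle(rng):
    pts = np.vstack([
        rng.normal([0, 0], 0.05, size=(3, 2)),
        rng.normal([4, 4], 0.05, size=(3, 2)),
    ])
    f = zscale(pts)
    model = kmeans_fit(f, k=2, seed=1)
    assert model.wss == pytest.approx(_min_wss_two_coloring(f.scaled), abs=1e-9)
    assert len(set(model.assignments[:3])) == 1 and len(set(model.assignments[3:])) == 1


def test_kmeans_duplicated_points_same_centroids_double_wss(rng):
    from spinemorph.clustering import ScaledFeatures

    pts = rng.uniform(0, 1, size=(60, 2))
    f1 = zscale(pts)
    m1 = kmeans_fit(f1, k=3, seed=2)
    # duplicate each point in scaled space, keeping the scaling params fixed
    f2 = ScaledFeatures(
        raw=np.vstack([pts, pts]),
        scaled=np.vstack([f1.scaled, f1.scaled]),
        mean=f1.mean,
        sd=f1.sd,
    )
    m2 = kmeans_fit(f2, k=3, seed=2)
    c1 = sorted(map(tuple, np.round(m1.centroids_scaled, 9)))
    c2 = sorted(map(tuple, np.round(m2.centroids_scaled, 9)))
    np.testing.assert_allclose(c1, c2, atol=1e-6)
    assert m2.wss == pytest.approx(2 * m1.wss, rel=1e-6)


def test_kmeans_centroid_fixed_point(rng):
    f = zscale(rng.uniform(0, 2, size=(300, 2)))
    model = kmeans_fit(f, k=4, seed=3)
    for j in range(4):
        members = f.scaled[model.assignments == j]
        np.testing.assert_allclose(
            members.mean(axis=0), model.centroids_scaled[j], atol=1e-9
        )


def test_kmeans_seed_reproducibility(rng):
    f = zscale(rng.uniform(0, 2, size=(400, 2)))
    a = kmeans_fit(f, k=3, seed=7)
    b = kmeans_fit(f, k=3, seed=7)
    assert (a.assignments == b.assignments).all()
    np.testing.assert_array_equal(a.centroids_scaled, b.centroids_scaled)


def test_kmeans_k_out_of_range(rng):
    f = zscale(rng.uniform(0, 1, size=(5, 2)))
    with pytest.raises(ValueError):
        kmeans_fit(f, k=6)


@pytest.mark.parametrize("n_blobs", [2, 3])
def test_select_k_recovers_well_separated_blobs(rng, n_blobs):
    # centres spread over both axes so per-axis z-scaling keeps blobs round
    centers = np.array([[0, 0], [8, 8], [8, 0]])[:n_blobs]
    pts = np.vstack([rng.normal(c, 0.3, size=(400 // n_blobs, 2)) for c in centers])
    f = zscale(pts)
    sel = select_k(f, k_range=range(2, 7), seed=0)
    assert sel.best_k == n_blobs
    # WSS is non-increasing in k for the reported diagnostics
    assert all(b <= a + 1e-9 for a, b in zip(sel.wss, sel.wss[1:]))


def test_silhouette_matches_direct_pairwise_oracle(rng):
    f = zscale(rng.uniform(0, 1, size=(150, 2)))
    model = kmeans_fit(f, k=3, seed=4)
    X, lab = f.scaled, model.assignments
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    sils = []
    for i in range(len(X)):
        own = lab[i]
        same = (lab == own) & (np.arange(len(X)) != i)
        if not same.any():
            sils.append(0.0)
            continue
        a = d[i, same].mean()
        b = min(d[i, lab == other].mean() for other in set(lab) - {own})
        sils.append((b - a) / max(a, b))
    assert model.silhouette_mean == pytest.approx(np.mean(sils), abs=1e-9)


@pytest.mark.parametrize(
    "centroids,expected",
    [
        # published hippocampal centroids (width, length): small, long, wide
        ([(0.42, 0.501), (0.555, 1.46), (0.789, 0.893)], ["small", "long", "wide"]),
        # published prefrontal-cortex centroids
        ([(0.503, 0.629), (0.644, 1.69), (0.925, 1.12)], ["small", "long", "wide"]),
    ],
)
def test_label_clusters_published_centroids(centroids, expected):
    labels = label_clusters(np.array(centroids))
    assert [labels[i] for i in range(3)] == expected


def test_label_clusters_order_invariant():
    c = np.array([(0.42, 0.501), (0.555, 1.46), (0.789, 0.893)])
    base = label_clusters(c)
    for perm in itertools.permutations(range(3)):
        lab = label_clusters(c[list(perm)])
        assert [lab[i] for i in range(3)] == [base[p] for p in perm]


def test_label_clusters_tie_errors():
    with pytest.raises(ValueError, match="tie"):
        label_clusters([(0.4, 1.0), (0.5, 1.0), (0.6, 0.5)])
    with pytest.raises(ValueError, match="tie"):
        label_clusters([(0.4, 0.5), (0.4, 0.6), (0.5, 1.5)])


def test_centroid_recovery_on_default_mixture(rng):
    """Fitted raw-unit centroids land near the generating component means."""
    cfg = default_region_config("hippocampus_CA1")
    dims = sample_spine_dimensions(cfg, 2000, rng)
    f = zscale(dims)
    model = kmeans_fit(f, k=3, seed=0)
    gen_means = np.array([(c.mean_width, c.mean_length) for c in cfg.components])
    for g in gen_means:
        err = np.abs(model.centroids_raw - g).max(axis=1).min()
        assert err < 0.05
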