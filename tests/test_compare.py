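"""Per-neuron summaries, Student's t, Holm–Bonferroni and strain comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from spinemorph.compare import (
    compare_strains,
    holm_bonferroni,
    neuron_cluster_counts,
    neuron_density,
    student_t,
)
from spinemorph.datamodel import Dataset


def _segments(rows):
    cols = ["strain", "mouse_id", "region", "neuron_id", "compartment", "position",
            "segment_id", "segment_length_um", "spine_count"]
    return Dataset(segments=pd.DataFrame(rows, columns=cols)).validate()


def test_density_single_segment():
    ds = _segments([("A", "m1", "hippocampus_CA1", "n1", "apical", "proximal", "d1", 25.0, 30)])
    d = neuron_density(ds)
    total = d[(d["compartment"] == "all")]["value"].iloc[0]
    assert total == pytest.approx(30.0)


def test_density_two_segments_mean():
    ds = _segments([
        ("A", "m1", "hippocampus_CA1", "n1", "apical", "proximal", "d1", 25.0, 20),
        ("A", "m1", "hippocampus_CA1", "n1", "apical", "distal", "d2", 25.0, 30),
    ])
    d = neuron_density(ds)
    assert d[d["compartment"] == "all"]["value"].iloc[0] == pytest.approx(25.0)
    assert d[d["compartment"] == "apical"]["value"].iloc[0] == pytest.approx(25.0)


def test_density_normalizes_segment_length():
    ds = _segments([("A", "m1", "hippocampus_CA1", "n1", "basal", "distal", "d1", 10.0, 10)])
    d = neuron_density(ds)
    assert d[d["compartment"] == "all"]["value"].iloc[0] == pytest.approx(25.0)


def test_density_matches_groupby_oracle(small_dataset):
    d = neuron_density(small_dataset)
    # density derives from the 25-μm counting segments only
    seg = small_dataset.segments[small_dataset.segments["segment_length_um"] == 25.0]
    for _, row in d[d["compartment"] == "all"].sample(10, random_state=0).iterrows():
        sub = seg[
            (seg["strain"] == row["strain"]) & (seg["mouse_id"] == row["mouse_id"])
            & (seg["region"] == row["region"]) & (seg["neuron_id"] == row["neuron_id"])
        ]
        oracle = (sub["spine_count"] / sub["segment_length_um"] * 25).mean()
        assert row["value"] == pytest.approx(oracle)


def test_student_t_identical_groups():
    res = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0 and res.p == pytest.approx(1.0) and res.df == 4


def test_student_t_separation_limit():
    res = student_t([1.0, 1.001, 0.999], [101.0, 101.001, 100.999])
    assert res.p < 1e-12


def test_student_t_zero_variance_conventions():
    flagged = student_t([2.0, 2.0], [2.0, 2.0])
    assert flagged.flagged and flagged.p == 1.0
    with pytest.raises(ValueError):
        student_t([2.0, 2.0], [3.0, 3.0])


def test_student_t_matches_closed_form(rng):
    x = rng.normal(0, 1, 10)
    y = rng.normal(0.5, 1, 10)
    res = student_t(x, y)
    sp2 = ((9 * x.var(ddof=1)) + (9 * y.var(ddof=1))) / 18
    t_oracle = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 10 + 1 / 10))
    from scipy.stats import t as tdist

    p_oracle = 2 * tdist.sf(abs(t_oracle), 18)
    assert res.t == pytest.approx(t_oracle, abs=1e-12)
    assert res.p == pytest.approx(p_oracle, abs=1e-12)
    assert res.df == 18


def test_student_t_antisymmetric(rng):
    x, y = rng.normal(size=8), rng.normal(size=11)
    assert student_t(x, y).t == pytest.approx(-student_t(y, x).t, abs=1e-12)


def test_holm_single_p_identity():
    adj, rej = holm_bonferroni([0.03])
    assert adj.tolist() == [0.03] and rej.tolist() == [True]


def test_holm_two_values_hand_computed():
    adj, _ = holm_bonferroni([0.01, 0.04])
    np.testing.assert_allclose(adj, [0.02, 0.04], atol=1e-12)


def _holm_oracle(p):
    """Direct step-down definition: running max of min(1, (m−i)·p_(i))."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    vals = [(m - i) * p[order[i]] for i in range(m)]
    run = np.minimum(1.0, np.maximum.accumulate(vals))
    out = np.empty(m)
    out[order] = run
    return out


def test_holm_random_vectors_match_direct_definition(rng):
    for _ in range(50):
        p = rng.uniform(0, 1, 6)
        adj, rej = holm_bonferroni(p)
        np.testing.assert_allclose(adj, _holm_oracle(p), atol=1e-9)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        # Holm never rejects more than the uncorrected α-level test
        assert rej.sum() <= (p <= 0.05).sum()


def test_holm_rejects_invalid_p():
    with pytest.raises(ValueError):
        holm_bonferroni([0.1, 1.2])


def _summaries(values_by_strain, metric="m", region="hippocampus_CA1"):
    rows = []
    for strain, values in values_by_strain.items():
        for i, v in enumerate(values):
            rows.append((strain, f"m{i//5}", region, f"n{i}", "all", metric, v))
    return pd.DataFrame(
        rows,
        columns=["strain", "mouse_id", "region", "neuron_id", "compartment", "metric", "value"],
    )


def test_compare_identical_strains_nothing_significant(rng):
    vals = rng.normal(10, 2, 20)
    s = _summaries({"A": vals, "B": vals})
    res = compare_strains(s, region="hippocampus_CA1")
    assert not res["significant"].any()
    assert res["t"].iloc[0] == 0.0


def test_compare_single_metric_family_adjusted_equals_raw(rng):
    s = _summaries({"A": rng.normal(10, 2, 20), "B": rng.normal(12, 2, 20)})
    res = compare_strains(s, region="hippocampus_CA1")
    assert res["p_adj"].iloc[0] == pytest.approx(res["p_raw"].iloc[0])


def test_compare_reports_group_means_and_sd(rng):
    a, b = rng.normal(10, 2, 15), rng.normal(11, 2, 15)
    res = compare_strains(_summaries({"A": a, "B": b}), region="hippocampus_CA1")
    assert res["mean_A"].iloc[0] == pytest.approx(a.mean())
    assert res["sd_B"].iloc[0] == pytest.approx(b.std(ddof=1))


def test_neuron_cluster_counts_requires_labels(small_dataset):
    with pytest.raises(ValueError, match="cluster_label"):
        neuron_cluster_counts(small_dataset.spines)


def test_cluster_counts_sum_to_spine_totals(small_dataset):
    from spinemorph.clustering import cluster_spines

    _, spines, _ = cluster_spines(small_dataset, "hippocampus_CA1", k=3, seed=0)
    counts = neuron_cluster_counts(spines)
    total = counts[counts["compartment"] == "all"]["value"].sum()
    assert total == len(spines)
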