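"""Rule-based spine classification: binary criteria and Risher-style scheme."""

import numpy as np
import pandas as pd
import pytest

from spinemorph.classify import (
    RISHER_CLASSES,
    class_frequencies,
    classify_binary,
    classify_risher,
)
from spinemorph.datamodel import Dataset
from spinemorph.synthetic import generate_dataset

from conftest import small_config


@pytest.mark.parametrize(
    "length,width,expected",
    [
        (2.5, 0.5, ("filopodia_like", "non_mushroom_head_like")),
        (2.0, 0.6, ("non_filopodia_like", "non_mushroom_head_like")),  # boundary: ≤ classes
        (1.0, 0.7, ("non_filopodia_like", "mushroom_head_like")),
        (2.0001, 0.6001, ("filopodia_like", "mushroom_head_like")),
    ],
)
def test_binary_thresholds(length, width, expected):
    assert classify_binary(length, width) == expected


def test_binary_grid_matches_threshold_oracle():
    L, W = np.meshgrid(np.arange(0.1, 4.05, 0.1), np.arange(0.1, 2.05, 0.1))
    lc, hc = classify_binary(L.ravel(), W.ravel())
    assert ((lc == "filopodia_like") == (L.ravel() > 2.0)).all()
    assert ((hc == "mushroom_head_like") == (W.ravel() > 0.6)).all()


@pytest.mark.parametrize(
    "length,width,branched,expected",
    [
        (2.5, 0.5, False, "filopodia"),      # L>2, LWR=5>1, W≤0.6
        (0.5, 0.8, False, "mushroom_wide"),  # W>0.6, LWR=0.625<1
        (1.5, 0.7, False, "mushroom_medium"),  # W>0.6, LWR>1
        (0.7, 0.7, False, "mushroom_medium"),  # LWR exactly 1: printed LWR<1 is strict
        (0.5, 0.55, False, "stubby"),        # W≤0.6, LWR≈0.909≤1
        (1.5, 0.5, False, "long_thin"),      # 1<L≤2, W≤0.6
        (0.8, 0.4, False, "thin"),           # L≤1, W≤0.6, LWR=2>1
        (2.5, 0.5, True, "branched"),
        (0.3, 0.3, True, "branched"),
    ],
)
def test_risher_rules(length, width, branched, expected):
    assert classify_risher(length, width, branched) == expected


def test_risher_partition_total_exclusive_and_complete():
    """Every (L, W, branched) cell gets exactly one label; all 7 realized."""
    L, W = np.meshgrid(np.arange(0.05, 4.001, 0.05), np.arange(0.05, 2.001, 0.05))
    labels = classify_risher(L.ravel(), W.ravel(), False)
    assert set(labels) | {"branched"} == set(RISHER_CLASSES)
    assert classify_risher(1.0, 0.5, True) == "branched"
    # exclusivity re-check against the written rule set, cell by cell
    lwr = L.ravel() / W.ravel()
    mushroom = W.ravel() > 0.6
    assert (np.isin(labels, ["mushroom_wide", "mushroom_medium"]) == mushroom).all()
    assert ((labels == "stubby") == (~mushroom & (lwr <= 1))).all()
    assert ((labels == "filopodia") == (~mushroom & (lwr > 1) & (L.ravel() > 2))).all()


def test_risher_consistent_with_binary_scheme():
    rng = np.random.default_rng(5)
    L = rng.uniform(0.05, 4, 5000)
    W = rng.uniform(0.05, 2, 5000)
    risher = classify_risher(L, W, False)
    lc, hc = classify_binary(L, W)
    assert (lc[risher == "filopodia"] == "filopodia_like").all()
    mush = np.isin(risher, ["mushroom_medium", "mushroom_wide"])
    assert (hc[mush] == "mushroom_head_like").all()


def test_nonpositive_dimensions_rejected():
    with pytest.raises(ValueError):
        classify_binary(0.0, 0.5)
    with pytest.raises(ValueError):
        classify_risher(1.0, -0.1, False)


def _one_spine_dataset(length=2.5, width=0.5):
    row = {
        "strain": "C57BL_6J", "mouse_id": "m01", "region": "hippocampus_CA1",
        "neuron_id": "n01", "compartment": "apical", "position": "proximal",
        "segment_id": "m01", "length_um": length, "width_um": width, "branched": False,
    }
    return Dataset(spines=pd.DataFrame([row])).validate()


def test_frequencies_single_spine_counts_one_class():
    freq = class_frequencies(_one_spine_dataset(), "binary", group_by=["strain"])
    assert freq["count"].sum() == 1
    hit = freq[freq["count"] == 1]
    assert hit["shape_class"].iloc[0] == "filopodia_like|non_mushroom_head_like"
    assert (freq[freq["count"] == 0]["count"] == 0).all() and len(freq) == 4


def test_frequencies_double_dataset_doubles_counts(small_dataset):
    freq1 = class_frequencies(small_dataset, "risher", group_by=["strain", "region"])
    doubled = Dataset(
        spines=pd.concat([small_dataset.spines] * 2, ignore_index=True),
        segments=small_dataset.segments,
    )
    freq2 = class_frequencies(doubled, "risher", group_by=["strain", "region"])
    merged = freq1.merge(freq2, on=["strain", "region", "shape_class"], suffixes=("_1", "_2"))
    assert (merged["count_2"] == 2 * merged["count_1"]).all()


def test_frequencies_match_per_record_tally(small_dataset):
    """Group counts equal a brute-force reclassification tally per record."""
    freq = class_frequencies(small_dataset, "risher", group_by=["strain", "compartment"])
    for _, row in freq.iterrows():
        sub = small_dataset.spines
        sub = sub[(sub["strain"] == row["strain"]) & (sub["compartment"] == row["compartment"])]
        tally = sum(
            classify_risher(r.length_um, r.width_um, r.branched) == row["shape_class"]
            for r in sub.itertuples()
        )
        assert tally == row["count"]
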