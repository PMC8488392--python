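"""Rule-based spine shape classification.

Two schemes are implemented, both operating on spine length L (base to tip,
μm), head width W (broadest part of the head, μm), and their ratio
LWR = L/W:

* **binary** — two independent dichotomies: filopodia-like length
  (L > 2 μm) vs non-filopodia-like (L ≤ 2 μm), and mushroom-head-like width
  (W > 0.6 μm) vs non-mushroom-head-like (W ≤ 0.6 μm).

* **risher** — a seven-class partition in the style of Risher's 2-D scheme:
  filopodia, long_thin, thin, stubby, mushroom_medium, mushroom_wide and
  branched. The printed rules overlap (a short wide spine can satisfy both
  the stubby and the mushroom-wide conditions), so classes are assigned with
  a fixed precedence that makes the rules a total partition:

  branched → mushroom (W > 0.6: wide if LWR < 1 else medium) →
  stubby (LWR ≤ 1) → filopodia (L > 2) → long_thin (L > 1) → thin.

  Head width takes precedence because mushroom identity is width-primary;
  once W ≤ 0.6 and LWR > 1 are established, the remaining classes reduce to
  pure length cut-offs. All thresholds are exact comparisons (boundary
  values fall into the "≤" class) with no epsilon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import Dataset

#: Length above which a spine counts as filopodia-like (μm).
FILOPODIA_LENGTH_UM = 2.0
#: Head width above which a spine counts as mushroom-head-like (μm).
MUSHROOM_WIDTH_UM = 0.6

BINARY_LENGTH_CLASSES = ("filopodia_like", "non_filopodia_like")
BINARY_HEAD_CLASSES = ("mushroom_head_like", "non_mushroom_head_like")
RISHER_CLASSES = (
    "filopodia",
    "long_thin",
    "thin",
    "stubby",
    "mushroom_medium",
    "mushroom_wide",
    "branched",
)


def _check_positive(length, width):
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("spine length and width must be positive")
    return length, width


def classify_binary(length, width) -> tuple:
    """Binary classification of spines by length and by head width.

    Returns ``(length_class, head_class)``; each element is a string for
    scalar input or an array of strings for array input.
    """
    length, width = _check_positive(length, width)
    length_class = np.where(length > FILOPODIA_LENGTH_UM, *BINARY_LENGTH_CLASSES)
    head_class = np.where(width > MUSHROOM_WIDTH_UM, *BINARY_HEAD_CLASSES)
    if length_class.ndim == 0:
        return str(length_class), str(head_class)
    return length_class, head_class


def classify_risher(length, width, branched=False):
    """Seven-class Risher-style classification (see module docstring).

    Scalar inputs return a single class name; array inputs an array.
    """
    length, width = _check_positive(length, width)
    branched_arr = np.broadcast_to(np.asarray(branched, dtype=bool), length.shape)
    lwr = length / width
    conditions = [
        branched_arr,
        (width > MUSHROOM_WIDTH_UM) & (lwr < 1.0),
        width > MUSHROOM_WIDTH_UM,
        lwr <= 1.0,
        length > FILOPODIA_LENGTH_UM,
        length > 1.0,
    ]
    choices = ["branched", "mushroom_wide", "mushroom_medium", "stubby", "filopodia", "long_thin"]
    out = np.select(conditions, choices, default="thin")
    return str(out) if out.ndim == 0 else out


def classify_spines(dataset: Dataset, scheme: str) -> pd.DataFrame:
    """Spine table with classification columns appended.

    ``scheme="binary"`` adds ``length_class`` and ``head_class``;
    ``scheme="risher"`` adds ``risher_class``.
    """
    df = dataset.spines.copy()
    L = df["length_um"].to_numpy()
    W = df["width_um"].to_numpy()
    if scheme == "binary":
        if len(df):
            df["length_class"], df["head_class"] = classify_binary(L, W)
        else:
            df["length_class"] = df["head_class"] = pd.Series(dtype=str)
    elif scheme == "risher":
        if len(df):
            df["risher_class"] = classify_risher(L, W, df["branched"].to_numpy())
        else:
            df["risher_class"] = pd.Series(dtype=str)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected 'binary' or 'risher'")
    return df


def _class_labels(scheme: str) -> tuple[str, list[str]]:
    if scheme == "binary":
        labels = [f"{lc}|{hc}" for lc in BINARY_LENGTH_CLASSES for hc in BINARY_HEAD_CLASSES]
        return "shape_class", labels
    return "shape_class", list(RISHER_CLASSES)


def class_frequencies(dataset: Dataset, scheme: str, group_by: list[str]) -> pd.DataFrame:
    """Class counts and per-neuron means per group.

    For the binary scheme the four length × head cells are counted (class
    token ``"<length_class>|<head_class>"``). Every class appears in every
    observed group, with zero counts where absent; groups with no spines at
    all are not synthesised. Columns: *group_by*, ``shape_class``, ``count``,
    ``n_neurons``, ``mean_per_neuron``.
    """
    classified = classify_spines(dataset, scheme)
    col, labels = _class_labels(scheme)
    if scheme == "binary":
        classified[col] = classified["length_class"] + "|" + classified["head_class"]
    else:
        classified[col] = classified["risher_class"]
    if not len(classified):
        return pd.DataFrame(columns=[*group_by, col, "count", "n_neurons", "mean_per_neuron"])

    groups = classified.groupby(group_by, observed=True)
    records = []
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        n_neurons = sub.groupby(["strain", "mouse_id", "neuron_id"], observed=True).ngroups
        counts = sub[col].value_counts()
        for label in labels:
            c = int(counts.get(label, 0))
            records.append((*key, label, c, n_neurons, c / n_neurons))
    return pd.DataFrame(records, columns=[*group_by, col, "count", "n_neurons", "mean_per_neuron"])
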