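"""Soma morphometry: perimeter, area and the circularity index.

The circularity index CI = 4π·A / P² compares an outline's area A with the
area of a circle of the same perimeter P. CI equals 1.0 for a perfect circle
of any radius and decreases toward 0 for elongated or irregular somata; the
isoperimetric inequality guarantees CI ≤ 1 for every simple outline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .datamodel import ANATOMY_KEYS, Dataset


class GeometryError(ValueError):
    """A polygon outline is degenerate or self-intersecting."""


def circularity(perimeter, area):
    """Circularity index 4π·area/perimeter² of a closed outline.

    Accepts scalars or arrays (μm and μm²); inputs must be positive.
    """
    perimeter = np.asarray(perimeter, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(perimeter <= 0) or np.any(area <= 0):
        raise ValueError("perimeter and area must be positive")
    out = 4.0 * np.pi * area / perimeter**2
    return float(out) if out.ndim == 0 else out


def polygon_metrics(vertices) -> tuple[float, float]:
    """Perimeter and area (shoelace, orientation-independent) of a simple polygon.

    Parameters
    ----------
    vertices : sequence of (x, y) pairs in μm, in drawing order (either
        orientation); the closing edge back to the first vertex is implied.

    Returns
    -------
    (perimeter_um, area_um2)
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) vertices")
    poly = Polygon(pts)
    if poly.area == 0:
        raise GeometryError("vertices are collinear: zero-area outline")
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("self-intersecting polygon outline")
    return float(poly.exterior.length), float(poly.area)


def soma_metrics(dataset: Dataset) -> pd.DataFrame:
    """Per-soma metrics table: perimeter, area and circularity per neuron."""
    df = dataset.somata.copy()
    df["circularity"] = circularity(df["perimeter_um"].to_numpy(), df["area_um2"].to_numpy()) \
        if len(df) else pd.Series(dtype=float)
    return df


def summarize_soma(dataset: Dataset) -> pd.DataFrame:
    """Group means ± SD of soma metrics per strain × region.

    Values stay at neuron resolution upstream (see :func:`soma_metrics`), so
    users can also aggregate per mouse; this summary is the strain-level view.
    """
    metrics = soma_metrics(dataset)
    long = metrics.melt(
        id_vars=ANATOMY_KEYS,
        value_vars=["perimeter_um", "area_um2", "circularity"],
        var_name="metric",
    )
    g = long.groupby(["strain", "region", "metric"], observed=True)["value"]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    return out
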