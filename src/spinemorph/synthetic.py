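"""Synthetic two-strain morphometry datasets.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised without access to raw Golgi
measurements. Per strain × region it draws:

* spine (width, length) pairs from a 3-component truncated bivariate-normal
  mixture with independent axes, truncated by rejection to the observed
  supports width ∈ (0, 2] μm and length ∈ (0, 4] μm. The default component
  means sit at the published cluster centroids of each region; the per-axis
  SDs (0.12 μm width, 0.25 μm length) are a calibration of the generator,
  not measured values.
* per-segment spine counts from Poisson distributions: 12 density segments
  of 25 μm and 20 morphology segments of 10 μm per neuron (3 and 5 per
  compartment × position respectively), 5 traced neurons per mouse, 4 mice
  per strain — the study's sampling design, yielding ≈ 6,000 measured
  spines per strain per region.
* branched flags as Bernoulli draws.
* soma outlines as 64-vertex ellipse polygons with multiplicative radial
  noise, the axis ratio solved numerically so the polygon hits a target
  circularity drawn per soma; perimeter is rescaled to a target draw.

Randomness flows from a single master seed through deterministic
per-(strain, region, mouse, neuron) sub-streams, so datasets are exactly
reproducible and partially regenerable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .datamodel import Dataset
from .soma import polygon_metrics

STRAIN_NEUROTYPICAL = "C57BL_6J"
STRAIN_AUTISTIC_LIKE = "C58J"

#: Published k = 3 cluster centroids per region, as (width μm, length μm).
HIPPOCAMPUS_CENTROIDS = {
    "small": (0.42, 0.501),
    "long": (0.555, 1.46),
    "wide": (0.789, 0.893),
}
PFC_CENTROIDS = {
    "small": (0.503, 0.629),
    "long": (0.644, 1.69),
    "wide": (0.925, 1.12),
}

#: Generator calibration: per-axis component SDs (μm).
DEFAULT_SD_WIDTH = 0.12
DEFAULT_SD_LENGTH = 0.25

WIDTH_SUPPORT = (0.0, 2.0)
LENGTH_SUPPORT = (0.0, 4.0)


class ConfigError(ValueError):
    """The synthetic configuration is inconsistent or infeasible."""


@dataclass
class MixtureComponent:
    """One truncated-normal mixture component of spine dimensions."""

    mean_width: float
    mean_length: float
    weight: float
    sd_width: float = DEFAULT_SD_WIDTH
    sd_length: float = DEFAULT_SD_LENGTH


@dataclass
class SomaModel:
    """Target distribution of soma size and roundness."""

    perimeter_mean: float = 55.0   # μm
    perimeter_sd: float = 5.0
    circularity_mean: float = 0.85
    circularity_sd: float = 0.04
    n_vertices: int = 64
    radial_noise_sd: float = 0.015  # multiplicative, lowers circularity slightly


@dataclass
class StrainRegionConfig:
    """Generating parameters for one strain in one brain region."""

    components: list[MixtureComponent]
    density_mean_apical: float = 30.0   # Poisson mean spines per 25-μm segment
    density_mean_basal: float = 30.0
    morphology_mean: float = 15.0       # Poisson mean spines per 10-μm segment
    branched_fraction: float = 0.02
    soma: SomaModel = field(default_factory=SomaModel)

    def validate(self) -> None:
        w = sum(c.weight for c in self.components)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ConfigError(f"component weights must sum to 1, got {w}")
        for c in self.components:
            if c.sd_width <= 0 or c.sd_length <= 0:
                raise ConfigError("component SDs must be positive")
        if not 0 <= self.branched_fraction <= 1:
            raise ConfigError("branched_fraction must lie in [0, 1]")


@dataclass
class SyntheticConfig:
    """Full two-strain generating configuration.

    ``strains`` maps strain → region → :class:`StrainRegionConfig`. The
    sampling-design counts default to the study layout: 4 mice per strain,
    5 traced neurons per mouse (spines), 10 soma-only neurons per mouse,
    12 density segments (25 μm) and 20 morphology segments (10 μm) per
    traced neuron.
    """

    strains: dict[str, dict[str, StrainRegionConfig]]
    mice: int = 4
    neurons_per_mouse: int = 5
    somata_per_mouse: int = 10
    density_segments_per_neuron: int = 12
    morphology_segments_per_neuron: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not self.strains:
            raise ConfigError("at least one strain is required")
        for regions in self.strains.values():
            for cfg in regions.values():
                cfg.validate()
        if self.density_segments_per_neuron % 4 or self.morphology_segments_per_neuron % 4:
            raise ConfigError("segment counts must divide evenly over 2 compartments × 2 positions")


def default_region_config(region: str) -> StrainRegionConfig:
    """Baseline (neurotypical) configuration for one region."""
    centroids = HIPPOCAMPUS_CENTROIDS if region == "hippocampus_CA1" else PFC_CENTROIDS
    weights = {"small": 0.45, "long": 0.20, "wide": 0.35}
    components = [
        MixtureComponent(mean_width=w, mean_length=l, weight=weights[name])
        for name, (w, l) in centroids.items()
    ]
    density = 30.0 if region == "hippocampus_CA1" else 27.0
    return StrainRegionConfig(
        components=components,
        density_mean_apical=density,
        density_mean_basal=density,
    )


PRESETS = ("null_twostrain", "paper_like_effect")


def preset(name: str) -> SyntheticConfig:
    """Named two-strain study configurations.

    ``null_twostrain`` gives both strains identical generating parameters.
    ``paper_like_effect`` shifts the autistic-like strain the way the study
    reports: in the hippocampus, +0.15 mixture weight on the small component
    taken from the wide component; in the prefrontal cortex, reduced spine
    density, mostly on apical dendrites.
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {list(PRESETS)}")
    base = {
        "hippocampus_CA1": default_region_config("hippocampus_CA1"),
        "pfc_II_III": default_region_config("pfc_II_III"),
    }
    if name == "null_twostrain":
        strains = {
            STRAIN_NEUROTYPICAL: {r: replace(c) for r, c in base.items()},
            STRAIN_AUTISTIC_LIKE: {r: replace(c) for r, c in base.items()},
        }
        return SyntheticConfig(strains=strains)

    hip = base["hippocampus_CA1"]
    shifted = [
        replace(c, weight=c.weight + d)
        for c, d in zip(hip.components, (+0.15, 0.0, -0.15))  # small, long, wide
    ]
    hip_effect = replace(hip, components=shifted)
    pfc = base["pfc_II_III"]
    pfc_effect = replace(
        pfc,
        components=[replace(c) for c in pfc.components],
        density_mean_apical=pfc.density_mean_apical * 0.85,
        density_mean_basal=pfc.density_mean_basal * 0.97,
    )
    strains = {
        STRAIN_NEUROTYPICAL: {r: replace(c) for r, c in base.items()},
        STRAIN_AUTISTIC_LIKE: {"hippocampus_CA1": hip_effect, "pfc_II_III": pfc_effect},
    }
    return SyntheticConfig(strains=strains)


def sample_spine_dimensions(
    cfg: StrainRegionConfig,
    n: int,
    rng: np.random.Generator,
    return_components: bool = False,
):
    """Draw n (width, length) pairs from the truncated mixture by rejection.

    Raises :class:`ConfigError` if the truncation acceptance falls below 1%.
    """
    means = np.array([(c.mean_width, c.mean_length) for c in cfg.components])
    sds = np.array([(c.sd_width, c.sd_length) for c in cfg.components])
    weights = np.array([c.weight for c in cfg.components])
    comp = rng.choice(len(cfg.components), size=n, p=weights)
    out = np.empty((n, 2))
    todo = np.arange(n)
    tries = 0
    while todo.size:
        tries += 1
        if tries > 200:  # acceptance below ~1% over repeated rounds
            raise ConfigError("truncation acceptance below 1%; adjust component means/SDs")
        draw = rng.normal(means[comp[todo]], sds[comp[todo]])
        ok = (
            (draw[:, 0] > WIDTH_SUPPORT[0])
            & (draw[:, 0] <= WIDTH_SUPPORT[1])
            & (draw[:, 1] > LENGTH_SUPPORT[0])
            & (draw[:, 1] <= LENGTH_SUPPORT[1])
        )
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    if return_components:
        return out, comp
    return out


def _ellipse_axis_ratio(target_ci: float) -> float:
    """Axis ratio q of an ellipse whose circularity equals *target_ci*.

    For semi-axes (a, qa): CI = π²·q / (4·E(1−q²)²) with E the complete
    elliptic integral of the second kind; CI(1) = 1 and CI is monotone in q.
    """
    def f(q: float) -> float:
        return math.pi**2 * q / (4.0 * special.ellipe(1.0 - q * q) ** 2) - target_ci

    if target_ci >= 1.0:
        return 1.0
    return float(optimize.brentq(f, 1e-3, 1.0))


def generate_soma_polygon(
    rng: np.random.Generator, soma: SomaModel
) -> tuple[np.ndarray, float, float]:
    """One noisy elliptical soma outline; returns (vertices, perimeter, area)."""
    target_ci = float(np.clip(rng.normal(soma.circularity_mean, soma.circularity_sd), 0.3, 0.995))
    target_p = max(float(rng.normal(soma.perimeter_mean, soma.perimeter_sd)), 5.0)
    q = _ellipse_axis_ratio(target_ci)
    theta = np.linspace(0.0, 2.0 * math.pi, soma.n_vertices, endpoint=False)
    # polar radius of an ellipse with semi-axes (1, q), then multiplicative noise
    r = q / np.sqrt((q * np.cos(theta)) ** 2 + np.sin(theta) ** 2)
    r *= 1.0 + rng.normal(0.0, soma.radial_noise_sd, size=theta.size)
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    p, a = polygon_metrics(verts)
    scale = target_p / p
    verts = verts * scale
    return verts, target_p, a * scale * scale


_LAYOUT = {
    # (segments per compartment × position) are filled as apical/basal × proximal/distal
    "density": (25.0, "d"),
    "morphology": (10.0, "m"),
}


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate a full dataset (spines, segments, somata) from *config*."""
    config.validate()
    spine_frames: list[pd.DataFrame] = []
    seg_frames: list[pd.DataFrame] = []
    soma_rows: list[dict] = []

    strain_names = list(config.strains)
    for si, strain in enumerate(strain_names):
        for ri, (region, cfg) in enumerate(sorted(config.strains[strain].items())):
            _check_feasible(cfg)
            for mouse in range(config.mice):
                mouse_id = f"m{mouse + 1:02d}"
                for neuron in range(config.neurons_per_mouse):
                    rng = np.random.default_rng([config.seed, si, ri, mouse, neuron])
                    neuron_id = f"n{neuron + 1:02d}"
                    spines, segs = _generate_neuron(
                        rng, config, cfg, strain, mouse_id, region, neuron_id
                    )
                    spine_frames.append(spines)
                    seg_frames.append(segs)
                for neuron in range(config.somata_per_mouse):
                    rng = np.random.default_rng([config.seed, si, ri, mouse, 1000 + neuron])
                    _, p, a = generate_soma_polygon(rng, cfg.soma)
                    soma_rows.append(
                        {
                            "strain": strain,
                            "mouse_id": mouse_id,
                            "region": region,
                            "neuron_id": f"s{neuron + 1:02d}",
                            "perimeter_um": p,
                            "area_um2": a,
                        }
                    )

    from .datamodel import empty_table

    spines = pd.concat(spine_frames, ignore_index=True) if spine_frames else empty_table("spines")
    segments = pd.concat(seg_frames, ignore_index=True) if seg_frames else empty_table("segments")
    ds = Dataset(
        spines=spines,
        segments=segments,
        somata=pd.DataFrame(soma_rows) if soma_rows else empty_table("somata"),
        provenance=f"spinemorph.synthetic generate_dataset(seed={config.seed})",
    )
    return ds.validate()


def _check_feasible(cfg: StrainRegionConfig) -> None:
    # analytic acceptance of the truncation per component; reject configs <1%
    for c in cfg.components:
        from scipy.stats import norm

        acc_w = norm.cdf(WIDTH_SUPPORT[1], c.mean_width, c.sd_width) - norm.cdf(
            WIDTH_SUPPORT[0], c.mean_width, c.sd_width
        )
        acc_l = norm.cdf(LENGTH_SUPPORT[1], c.mean_length, c.sd_length) - norm.cdf(
            LENGTH_SUPPORT[0], c.mean_length, c.sd_length
        )
        if acc_w * acc_l < 0.01:
            raise ConfigError(
                f"truncation acceptance below 1% for component at "
                f"({c.mean_width}, {c.mean_length})"
            )


def _generate_neuron(rng, config, cfg, strain, mouse_id, region, neuron_id):
    """All segment and spine rows of one traced neuron, as two DataFrames."""
    seg_cols = {k: [] for k in ("compartment", "position", "segment_id",
                                "segment_length_um", "spine_count")}
    spine_frames = []
    for kind, (seg_len, tag) in _LAYOUT.items():
        per_cell = (
            config.density_segments_per_neuron if kind == "density"
            else config.morphology_segments_per_neuron
        ) // 4
        idx = 0
        for compartment in ("apical", "basal"):
            mean = (
                (cfg.density_mean_apical if compartment == "apical" else cfg.density_mean_basal)
                if kind == "density"
                else cfg.morphology_mean
            )
            for position in ("proximal", "distal"):
                counts = rng.poisson(mean, size=per_cell).astype(int)
                ids = [f"{tag}{idx + i + 1:02d}" for i in range(per_cell)]
                idx += per_cell
                seg_cols["compartment"] += [compartment] * per_cell
                seg_cols["position"] += [position] * per_cell
                seg_cols["segment_id"] += ids
                seg_cols["segment_length_um"] += [seg_len] * per_cell
                seg_cols["spine_count"] += counts.tolist()
                total = int(counts.sum())
                if kind != "morphology" or total == 0:
                    continue
                dims = sample_spine_dimensions(cfg, total, rng)
                branched = rng.random(total) < cfg.branched_fraction
                spine_frames.append(
                    pd.DataFrame(
                        {
                            "compartment": compartment,
                            "position": position,
                            "segment_id": np.repeat(ids, counts),
                            "length_um": dims[:, 1],
                            "width_um": dims[:, 0],
                            "branched": branched,
                        }
                    )
                )
    keys = {"strain": strain, "mouse_id": mouse_id, "region": region, "neuron_id": neuron_id}
    segs = pd.DataFrame(seg_cols)
    spines = (
        pd.concat(spine_frames, ignore_index=True)
        if spine_frames
        else pd.DataFrame(columns=["compartment", "position", "segment_id",
                                   "length_um", "width_um", "branched"])
    )
    for df in (segs, spines):
        for i, (col, val) in enumerate(keys.items()):
            df.insert(i, col, val)
    return spines[
        ["strain", "mouse_id", "region", "neuron_id", "compartment", "position",
         "segment_id", "length_um", "width_um", "branched"]
    ], segs[
        ["strain", "mouse_id", "region", "neuron_id", "compartment", "position",
         "segment_id", "segment_length_um", "spine_count"]
    ]
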