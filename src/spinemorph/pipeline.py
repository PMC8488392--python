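"""End-to-end orchestration of the morphometry pipeline.

``run_all`` executes simulate (optional) → soma metrics → density →
distribution comparison → classification (both schemes) → clustering →
strain comparison, writing one CSV per stage plus a plain-text summary and
a JSON run manifest. All randomness flows from the manifest seed; the CLI
and this module add no computation of their own beyond calling the stage
functions, so every output table is re-derivable directly from the library.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import class_frequencies
from .clustering import cluster_spines
from .compare import (
    compare_strains,
    neuron_class_counts,
    neuron_cluster_counts,
    neuron_density,
    neuron_soma,
)
from .datamodel import REGIONS, Dataset, ValidationError
from .distributions import compare_distributions
from .io import read_dataset, write_tables
from .soma import soma_metrics, summarize_soma
from .synthetic import generate_dataset, preset


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    inputs: dict[str, str] = field(default_factory=dict)    # path → sha256
    outputs: dict[str, str] = field(default_factory=dict)   # path → sha256
    log: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_all(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Run the whole pipeline; returns the populated manifest.

    Config keys (YAML mapping): ``seed`` (int), and either
    ``simulate: {preset: <name>}`` or ``inputs: <directory with CSV tables>``;
    optional ``cluster: {k: auto|int, k_range: [lo, hi]}``.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(config=cfg, seed=seed, started=_now())

    dataset = _stage_load(cfg, seed, out, manifest)
    _stage_soma(dataset, out, manifest)
    _stage_density(dataset, out, manifest)
    _stage_distributions(dataset, out, manifest)
    _stage_classify(dataset, out, manifest)
    clustered = _stage_cluster(dataset, cfg, seed, out, manifest)
    results = _stage_compare(dataset, clustered, out, manifest)
    _stage_summary(results, out, manifest)

    manifest.finished = _now()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.outputs[path.name] = _sha256(path)


def _stage_load(cfg, seed, out, manifest) -> Dataset:
    try:
        if "simulate" in cfg:
            name = cfg["simulate"].get("preset", "null_twostrain")
            sim_cfg = preset(name)
            sim_cfg.seed = seed
            dataset = generate_dataset(sim_cfg)
            manifest.log.append(f"simulate: preset={name} seed={seed}")
            paths = write_tables(dataset, out / "data")
            for p in paths.values():
                manifest.outputs[f"data/{p.name}"] = _sha256(p)
        elif "inputs" in cfg:
            directory = Path(cfg["inputs"])
            dataset = read_dataset(directory)
            for name in ("spines.csv", "segments.csv", "somata.csv"):
                p = directory / name
                if p.exists():
                    manifest.inputs[str(p)] = _sha256(p)
            manifest.log.append(f"load: {directory}")
        else:
            raise StageError("load: config needs either 'simulate' or 'inputs'")
    except (FileNotFoundError, ValidationError) as exc:
        raise StageError(f"load: {exc}") from exc
    manifest.log.append(
        f"load: {len(dataset.spines)} spines, {len(dataset.segments)} segments, "
        f"{len(dataset.somata)} somata"
    )
    return dataset


def _present_regions(dataset: Dataset) -> list[str]:
    present = set(dataset.spines["region"]) | set(dataset.segments["region"]) | set(
        dataset.somata["region"]
    )
    return [r for r in REGIONS if r in present]


def _stage_soma(dataset, out, manifest):
    try:
        if len(dataset.somata):
            _write(soma_metrics(dataset), out / "soma_metrics.csv", manifest)
            _write(summarize_soma(dataset), out / "soma_summary.csv", manifest)
            manifest.log.append(f"soma: {len(dataset.somata)} somata measured")
        else:
            manifest.log.append("soma: no soma traces, stage skipped")
    except Exception as exc:
        raise StageError(f"soma: {exc}") from exc


def _stage_density(dataset, out, manifest):
    try:
        dens = neuron_density(dataset)
        if len(dens):
            _write(dens, out / "density_per_neuron.csv", manifest)
        manifest.log.append(f"density: {len(dens)} neuron×compartment values")
    except Exception as exc:
        raise StageError(f"density: {exc}") from exc


def _stage_distributions(dataset, out, manifest):
    try:
        frames = []
        for region in _present_regions(dataset):
            if not len(dataset.subset(region=region).spines):
                continue
            for metric in ("length", "width"):
                for compartment in ("all", "apical", "basal"):
                    frames.append(
                        compare_distributions(dataset, metric, region, compartment)
                    )
        if frames:
            _write(pd.concat(frames, ignore_index=True), out / "ks_results.csv", manifest)
        manifest.log.append(f"distributions: {sum(len(f) for f in frames)} KS comparisons")
    except Exception as exc:
        raise StageError(f"distributions: {exc}") from exc


def _stage_classify(dataset, out, manifest):
    try:
        for scheme in ("binary", "risher"):
            freq = class_frequencies(
                dataset, scheme, group_by=["strain", "region", "compartment"]
            )
            _write(freq, out / f"classes_{scheme}.csv", manifest)
        manifest.log.append(f"classify: {len(dataset.spines)} spines, both schemes")
    except Exception as exc:
        raise StageError(f"classify: {exc}") from exc


def _stage_cluster(dataset, cfg, seed, out, manifest) -> dict[str, pd.DataFrame]:
    clustered: dict[str, pd.DataFrame] = {}
    ccfg = cfg.get("cluster", {})
    k = ccfg.get("k", 3)
    lo, hi = ccfg.get("k_range", [2, 8])
    try:
        centroid_frames = []
        for region in _present_regions(dataset):
            if len(dataset.subset(region=region).spines) < 3:
                continue
            model, spines, selection = cluster_spines(
                dataset, region, k=k, seed=seed, k_range=range(lo, hi + 1)
            )
            clustered[region] = spines
            cent = pd.DataFrame(model.centroids_raw, columns=["width_um", "length_um"])
            cent.insert(0, "region", region)
            cent.insert(1, "cluster", range(model.k))
            cent["label"] = [
                model.labels.get(i) if model.labels else "" for i in range(model.k)
            ]
            centroid_frames.append(cent)
            msg = f"cluster[{region}]: k={model.k} wss={model.wss:.1f} " \
                  f"silhouette={model.silhouette_mean:.3f}"
            if selection is not None:
                msg += f" (auto over k={selection.k_values})"
            manifest.log.append(msg)
        if clustered:
            _write(
                pd.concat(clustered.values(), ignore_index=True),
                out / "cluster_assignments.csv",
                manifest,
            )
            _write(pd.concat(centroid_frames, ignore_index=True), out / "centroids.csv", manifest)
    except Exception as exc:
        raise StageError(f"cluster: {exc}") from exc
    return clustered


def _family_metrics(summaries: pd.DataFrame, prefix: str) -> list[str]:
    return sorted(m for m in summaries["metric"].unique() if m.startswith(prefix))


def _stage_compare(dataset, clustered, out, manifest) -> pd.DataFrame:
    try:
        if len(dataset.strains) != 2:
            manifest.log.append("compare: needs exactly 2 strains, stage skipped")
            return pd.DataFrame()
        frames = []
        for region in _present_regions(dataset):
            families: list[tuple[str, pd.DataFrame, list[str] | None]] = []
            dens = neuron_density(dataset)
            if len(dens):
                families.append(("density", dens, None))
            if len(dataset.spines):
                for scheme in ("binary", "risher"):
                    cc = neuron_class_counts(dataset, scheme)
                    families.append((scheme, cc, _family_metrics(cc, f"{scheme}:")))
            if region in clustered and "cluster_label" in clustered[region].columns:
                cl = neuron_cluster_counts(clustered[region])
                families.append(("clusters", cl, _family_metrics(cl, "cluster:")))
            if len(dataset.somata):
                families.append(("soma", neuron_soma(dataset), None))
            for family, summaries, metrics in families:
                sub = summaries[summaries["region"] == region]
                if not len(sub):
                    continue
                for compartment in ("all", "apical", "basal"):
                    if not (sub["compartment"] == compartment).any():
                        continue
                    res = compare_strains(
                        sub, metrics=metrics, region=region, compartment=compartment
                    )
                    if len(res):
                        res.insert(0, "family", family)
                        frames.append(res)
        results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        if len(results):
            _write(results, out / "comparison.csv", manifest)
        manifest.log.append(f"compare: {len(results)} tests across families")
        return results
    except Exception as exc:
        raise StageError(f"compare: {exc}") from exc


def _stage_summary(results: pd.DataFrame, out, manifest):
    lines = ["spinemorph run summary", "======================", ""]
    lines += manifest.log
    lines.append("")
    if len(results):
        sig = results[results["significant"]]
        lines.append(f"significant strain differences (Holm-adjusted p < 0.05): {len(sig)}")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['family']}/{row['metric']} [{row['region']}, {row['compartment']}]: "
                f"t={row['t']:.2f}, p_adj={row['p_adj']:.4g}"
            )
    else:
        lines.append("no strain comparisons performed")
    path = out / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    manifest.outputs[path.name] = _sha256(path)
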