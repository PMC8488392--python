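import numpy as np
import pytest

from spinemorph.synthetic import SyntheticConfig, preset


def small_config(seed: int = 0, name: str = "null_twostrain") -> SyntheticConfig:
    """A scaled-down study layout for fast tests (same structure, fewer rows)."""
    cfg = preset(name)
    cfg.mice = 2
    cfg.neurons_per_mouse = 2
    cfg.somata_per_mouse = 2
    cfg.seed = seed
    for strain in cfg.strains:
        for region_cfg in cfg.strains[strain].values():
            region_cfg.morphology_mean = 5.0
    return cfg


def hippocampus_only(cfg: SyntheticConfig) -> SyntheticConfig:
    for strain in list(cfg.strains):
        cfg.strains[strain] = {"hippocampus_CA1": cfg.strains[strain]["hippocampus_CA1"]}
    return cfg


@pytest.fixture
def small_dataset():
    from spinemorph.synthetic import generate_dataset

    return generate_dataset(small_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20210920)
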