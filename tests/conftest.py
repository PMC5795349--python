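import numpy as np
import pandas as pd
import pytest

from phenomap import synth
from phenomap.design import generate_design


def small_config(**overrides) -> synth.SynthConfig:
    """Desk-scale conditions: small canvases and band count for fast tests."""
    kw = dict(
        seed=0,
        n_days=8,
        band_count=40,
        canvas=(200, 150),
        hyper_canvas=(80, 60),
        emergence_day=3,
    )
    kw.update(overrides)
    return synth.SynthConfig(**kw)


@pytest.fixture(scope="session")
def exp_small() -> synth.SyntheticExperiment:
    return synth.SyntheticExperiment(generate_design(0), small_config())


@pytest.fixture(scope="session")
def replicated_plants(exp_small) -> list[str]:
    """Plants of 6 genotypes that each have at least 3 replicates."""
    occ = exp_small.design.occupied
    genos = [g for g in occ["genotype"].unique()
             if (occ["genotype"] == g).sum() >= 3][:6]
    return occ[occ["genotype"].isin(genos)]["plant"].tolist()


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, exp_small, replicated_plants):
    """A small synthetic dataset tree in the released layout."""
    root = tmp_path_factory.mktemp("synthds") / "run"
    synth.simulate_dataset(
        root,
        exp_small.config,
        exp_small.design,
        plants=replicated_plants[:9],
        days=[2, 5, 8],
    )
    return root
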