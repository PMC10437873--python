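import numpy as np
import pandas as pd
import pytest

from thermenz import (
    AbundanceMatrix,
    SimulationConfig,
    default_substrate_map,
    generate_study,
)
from thermenz.scoring import load_printed_scores, load_study_sites


@pytest.fixture(scope="session")
def printed_scores() -> pd.DataFrame:
    """Per-sample cell/photosynthate sums of the 63-spring survey."""
    return load_printed_scores()


@pytest.fixture(scope="session")
def study_sites() -> pd.DataFrame:
    return load_study_sites()


@pytest.fixture(scope="session")
def substrate_map():
    return default_substrate_map()


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small synthetic study shared across tests (seed-fixed)."""
    cfg = SimulationConfig(n_sites=5, n_contigs_per_sample=120, seed=11)
    outdir = tmp_path_factory.mktemp("study")
    study, truth = generate_study(cfg, outdir)
    return cfg, study, truth


@pytest.fixture()
def toy_matrix() -> AbundanceMatrix:
    """3 families x 4 samples with hand-set values."""
    data = pd.DataFrame(
        {
            "S1": [2.0, 1.0, 3.0],
            "S2": [0.0, 4.0, 1.0],
            "S3": [5.0, 0.0, 0.0],
            "S4": [1.0, 1.0, 1.0],
        },
        index=["GH23", "GH5", "GH11"],
    )
    return AbundanceMatrix(scheme="CAZY", data=data)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
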