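import numpy as np
import pytest

from strandclass import ModelConfig, extract_features
from strandclass.pipeline import ExtractConfig
from strandclass.synth import SynthConfig, make_sequences, write_dataset


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """A small on-disk synthetic dataset: FASTA, labels and all three profile
    dialects for 12+12 proteins."""
    out = tmp_path_factory.mktemp("dataset")
    cfg = SynthConfig(n_pos=12, n_neg=12, seed=7)
    data = write_dataset(cfg, out)
    data["dir"] = out
    data["config"] = cfg
    return data


@pytest.fixture(scope="session")
def oaac_matrix_200():
    """Composition features for the standard study conditions: 100+100
    sequences, planted effect 0.3, seed 11."""
    cfg = SynthConfig(seed=11)
    records, labels = make_sequences(cfg)
    matrix, excluded = extract_features(
        records, labels, ExtractConfig(blocks=("OAAC",))
    )
    assert not excluded
    return matrix


@pytest.fixture
def fast_model():
    return ModelConfig(n_trees=100, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
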