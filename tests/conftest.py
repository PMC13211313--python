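import numpy as np
import pytest

from nmr2struct.model import ModelConfig
from nmr2struct.spectra import Nucleus, PpmGrid
from nmr2struct.synthetic import build_dataset
from nmr2struct.tokenizer import vocab_for_dataset

# Small grids so unit-level training/decoding tests stay fast; the
# default 10,000-point / 256x256 geometry is exercised separately.
SMALL_GRIDS = {
    "H1": PpmGrid(-2.0, 12.0, 500),
    "C13": PpmGrid(-10.0, 230.0, 500),
    "HSQC_H": PpmGrid(0.0, 12.0, 32),
    "HSQC_C": PpmGrid(0.0, 200.0, 32),
}

SMALL_GEOMETRY = {
    "H1": ("1d", 500),
    "C13": ("1d", 500),
    "HSQC": ("2d", (32, 32)),
}


def small_model_config(**overrides) -> ModelConfig:
    kwargs = dict(
        d_model=32,
        n_encoder_layers=2,
        n_decoder_layers=2,
        n_heads=2,
        ff_dim=64,
        patch_len_1d=50,
        patch_size_2d=8,
        patch_dropout_rate=0.5,
        max_decode_len=80,
        modalities=("H1",),
        geometry=dict(SMALL_GEOMETRY),
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 noiseless toy records on small grids, split 42/12/6."""
    return build_dataset(
        60,
        seed=5,
        modalities=("H1", "C13", "HSQC"),
        noise_sd=0.0,
        heavy_range=(5, 12),
        grids=SMALL_GRIDS,
    )


@pytest.fixture(scope="session")
def tiny_vocab(tiny_dataset):
    records = [r for split in tiny_dataset.values() for r in split.records]
    return vocab_for_dataset(records)
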