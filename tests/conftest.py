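import numpy as np
import pytest

from painattn.data import load_dataset
from painattn.pspi import stratified_split
from painattn.synth import SyntheticSpec, generate_dataset

TINY_STAGES = ((8,), (16,))
TINY_RESNET = (8, 16)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_flat_dataset(tmp_path_factory):
    """Small flat-background dataset shared across model/pipeline tests."""
    out = tmp_path_factory.mktemp("tiny_flat")
    spec = SyntheticSpec(
        frames_per_level={lvl: 12 for lvl in range(6)},
        image_size=32,
        background="flat",
        deformation_strength=1.0,
        seed=42,
    )
    records, manifest = generate_dataset(spec, out)
    return records, manifest, out


@pytest.fixture(scope="session")
def tiny_split(tiny_flat_dataset):
    records, _, _ = tiny_flat_dataset
    train_recs, test_recs = stratified_split(records, 0.8, seed=0)
    Xtr, ytr = load_dataset(train_recs, 32)
    Xte, yte = load_dataset(test_recs, 32)
    return (train_recs, Xtr, ytr), (test_recs, Xte, yte)
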