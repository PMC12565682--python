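import numpy as np
import pytest

from mvskel.curation import CurationConfig, curate_dataset
from mvskel.synthetic import PhantomConfig, generate_records
from mvskel.taxonomy import load_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def small_dataset(taxonomy):
    """Tiny curated phantom dataset (40 specimens, 32x32) for model tests."""
    config = PhantomConfig(
        n_specimens=40, image_size=(32, 32), abnormal_fraction=0.5, seed=5
    )
    records, labels = generate_records(config, taxonomy)
    return curate_dataset(records, taxonomy, CurationConfig(target_size=32))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
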