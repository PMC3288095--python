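import numpy as np
import pytest

from hmaxga import (
    FixtureSpec,
    build_filter_bank,
    compute_c1,
    default_c1_config,
    extract_patches,
    generate_dataset,
)


@pytest.fixture(scope="session")
def bank():
    return build_filter_bank()


@pytest.fixture(scope="session")
def c1_config():
    return default_c1_config()


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny planted-motif dataset for unit tests (fast to process)."""
    spec = FixtureSpec(n_pos=4, n_neg=4, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_c1_stack(small_dataset, bank, c1_config):
    ds, _ = small_dataset
    return [compute_c1(img, bank=bank, cfg=c1_config, source_id=i)
            for img, i in zip(ds.images, ds.ids)]


@pytest.fixture(scope="session")
def small_pdict(small_c1_stack):
    targets = [c1 for c1 in small_c1_stack if c1.source_id.startswith("pos")]
    return extract_patches(targets, sizes=(4, 8), count_per_size=6, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
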