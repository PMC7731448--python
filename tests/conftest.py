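import numpy as np
import pytest

from seedspec import PhantomConfig, SpectraTable, sample_spectra_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_table(rng):
    """A small unstructured spectra table (20 samples x 8 bands, 4 classes)."""
    spectra = rng.normal(0.3, 0.05, size=(20, 8))
    labels = np.repeat(["A", "B", "C", "D"], 5)
    return SpectraTable(spectra, labels, np.linspace(400, 1000, 8))


@pytest.fixture
def small_phantom():
    """A modest phantom table: 5 varieties x 12 seeds, 60 bands."""
    cfg = PhantomConfig(
        n_varieties=5, seeds_per_variety=12, n_bands=60, rng_seed=7
    )
    table, truth = sample_spectra_table(cfg)
    return cfg, table, truth
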