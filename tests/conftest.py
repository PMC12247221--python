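import numpy as np
import pytest

from specsim.chemstruct import pairwise_similarity_matrix
from specsim.spectra_io import Spectrum, load_default_adduct_map
from specsim.synthetic_fixtures import (
    EXCLUDED_LIBRARY_NAME,
    FixtureConfig,
    generate_benchmark_fixture,
    generate_structures,
)


@pytest.fixture(scope="session")
def adduct_map():
    return load_default_adduct_map()


@pytest.fixture(scope="session")
def small_cfg():
    return FixtureConfig(
        n_families=6, members_per_family=6, spectra_per_structure=2, seed=1
    )


@pytest.fixture(scope="session")
def small_structures(small_cfg):
    return generate_structures(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_structures):
    return pairwise_similarity_matrix(small_structures)


@pytest.fixture(scope="session")
def small_benchmark(small_cfg):
    """(all spectra incl. planted defects, structures, defect counts)."""
    return generate_benchmark_fixture(small_cfg)


def make_spectrum(
    spectrum_id="s",
    mz=(100.0, 200.0, 300.0, 400.0, 500.0),
    intensity=(0.5, 1.0, 0.3, 0.8, 0.4),
    precursor_mz=500.0,
    **kwargs,
):
    return Spectrum(
        spectrum_id=spectrum_id,
        mz=np.array(mz, dtype=float),
        intensity=np.array(intensity, dtype=float),
        precursor_mz=precursor_mz,
        **kwargs,
    )
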