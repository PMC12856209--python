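import numpy as np
import pytest

from pentaspec import BasisSet, generate_band_spectrum


@pytest.fixture(scope="session")
def cd_basis() -> BasisSet:
    """Parallel-G4 / non-G4-duplex CD basis on the default 1 nm grid."""
    g4 = generate_band_spectrum("parallel_G4_CD")
    duplex = generate_band_spectrum("non_G4_duplex_CD")
    return BasisSet.from_spectra(g4, duplex)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
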