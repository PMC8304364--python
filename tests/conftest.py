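import numpy as np
import pytest

from panelmarkov.markov import IntensityMatrix
from panelmarkov.reference import reference_intensity_matrix


@pytest.fixture(scope="session")
def reference_q() -> IntensityMatrix:
    """Generator reconstructed from the published jump/sojourn summaries."""
    return reference_intensity_matrix()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240613)


def random_generator_matrix(rng: np.random.Generator, lo: float = 0.02, hi: float = 0.5) -> IntensityMatrix:
    """A random valid 3x3 generator with all six transitions active."""
    return IntensityMatrix.from_rates(rng.uniform(lo, hi, size=6))
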