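import numpy as np
import pytest

from motiflogit import PositionProbabilityMatrix, SyntheticSpec, generate_library


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sharp_ppm():
    """A deterministic, information-rich 8-position motif."""
    probs = np.array(
        [
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.85, 0.05, 0.05],
            [0.05, 0.05, 0.85, 0.05],
            [0.05, 0.05, 0.05, 0.85],
            [0.70, 0.10, 0.10, 0.10],
            [0.10, 0.70, 0.10, 0.10],
            [0.10, 0.10, 0.70, 0.10],
            [0.10, 0.10, 0.10, 0.70],
        ]
    )
    return PositionProbabilityMatrix("sharp8", probs)


@pytest.fixture
def small_library():
    spec = SyntheticSpec(n_motifs=6, seed=7)
    return generate_library(spec)


def random_ppm(rng, length):
    """Random non-uniform PPM for property tests."""
    probs = rng.dirichlet(np.full(4, 0.5), size=length)
    return PositionProbabilityMatrix(f"rand{length}", probs)
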