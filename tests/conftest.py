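import numpy as np
import pytest

from emseg.objectives import NormalizedHistogram
from emseg.phantom import PhantomSpec, generate_phantom


def random_histogram(seed: int, L: int = 64) -> NormalizedHistogram:
    """Random integer-count histogram, reproducible per seed."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 1000, size=L)
    if counts.sum() == 0:
        counts[0] = 1
    total = int(counts.sum())
    return NormalizedHistogram(probs=counts / total, counts=counts, L=L,
                               total=total)


def histogram_from_probs(probs) -> NormalizedHistogram:
    """Histogram with given probabilities (synthetic counts, total 10^6)."""
    p = np.asarray(probs, dtype=float)
    total = 10**6
    counts = np.rint(p * total).astype(np.int64)
    return NormalizedHistogram(probs=p, counts=counts, L=len(p), total=total)


@pytest.fixture(scope="session")
def default_phantom():
    """256x256 T1-like phantom at 3% noise, seed 0, with ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(noise_sigma=0.0))
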