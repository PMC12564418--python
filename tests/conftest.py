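import numpy as np
import pytest

from meatspec.io import SpectraSet
from meatspec.synthetic import SyntheticConfig, generate


def make_set(x: np.ndarray, wavenumbers=None, labels=None) -> SpectraSet:
    """Wrap a bare matrix in a SpectraSet with default metadata."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if wavenumbers is None:
        wavenumbers = 600.0 + 2.0 * np.arange(p)
    if labels is None:
        labels = np.zeros(n, dtype=int)
        labels[n // 2:] = 1
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=x,
        sample_id=np.array([f"S{i:03d}" for i in range(n)], dtype=object),
        replicate_id=np.ones(n, dtype=int),
        label=labels,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse-grid generator config used by model-level tests."""
    return SyntheticConfig(n_per_class=20, grid=(900.0, 1800.0, 4.0), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate(small_cfg)


def blob_dataset(seed: int, n_per_class: int = 60, p: int = 30,
                 separation: float = 8.0, sd: float = 1.0) -> SpectraSet:
    """Two Gaussian classes with the given mean separation in units of sd."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    shift = separation * sd * direction
    x0 = rng.normal(0.0, sd, size=(n_per_class, p))
    x1 = rng.normal(0.0, sd, size=(n_per_class, p)) + shift
    x = np.vstack([x0, x1])
    labels = np.r_[np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    order = rng.permutation(2 * n_per_class)  # interleave so venetian sees both classes
    return make_set(x[order], labels=labels[order])
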