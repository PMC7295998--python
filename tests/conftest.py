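import numpy as np
import pytest

from fpsubnet.cohort import CohortSpec
from fpsubnet.io import Parcellation, default_parcellation

SMALL_SIZES = {
    "visual": 8,
    "somatomotor": 8,
    "dorsal-attention": 10,
    "ventral-attention": 6,
    "limbic": 6,
    "frontoparietal": 12,
    "default-mode": 12,
    "temporoparietal": 6,
}


@pytest.fixture(scope="session")
def parc400() -> Parcellation:
    return default_parcellation()


@pytest.fixture()
def parc_small() -> Parcellation:
    return default_parcellation(system_sizes=SMALL_SIZES)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def small_spec() -> CohortSpec:
    return CohortSpec(n_subjects=6, n_timepoints=80, seed=42)


def planted_block_network(
    rng: np.random.Generator,
    n_a: int = 30,
    n_b: int = 31,
    within: float = 0.5,
    between: float = 0.0,
    sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric weighted network with two planted blocks."""
    z = np.array([1] * n_a + [2] * n_b)
    mu = np.where(z[:, None] == z[None, :], within, between)
    c = rng.normal(mu, sd)
    c = np.triu(c, 1)
    return c + c.T, z
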