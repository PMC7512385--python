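import numpy as np
import pytest

from pottsmem.patterns import GenerationParams, generate, generate_uncorrelated


@pytest.fixture(scope="session")
def tiny_multiparent():
    """Small correlated pattern set with parent provenance (N=100, p=50)."""
    return generate(
        GenerationParams(
            N=100, S=3, a=0.25, n_parents=20, n_children=50, f=0.2, a_p=0.4,
            zeta=0.05, seed=2024,
        )
    )


@pytest.fixture(scope="session")
def tiny_uncorrelated():
    return generate_uncorrelated(
        GenerationParams(N=100, S=3, a=0.25, n_children=50, seed=2024)
    )


@pytest.fixture(scope="session")
def strict_distances():
    """Two-level block hierarchy: 4 clusters of 5, within 1.0 / between 2.0."""
    labels = np.repeat(np.arange(4), 5)
    D = np.where(labels[:, None] == labels[None, :], 1.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return D
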