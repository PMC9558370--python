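import numpy as np
import pytest

from alchemspace import (
    AffinityRecord,
    FeatureBlock,
    fixture_molecules,
    generate_landscape,
)


@pytest.fixture(scope="session")
def pyridine_series():
    """The packaged congeneric pyridine series, with 3-D coordinates."""
    return fixture_molecules(with_coords=True)


@pytest.fixture(scope="session")
def small_landscape():
    """A 300-ligand landscape used where the full default is overkill."""
    return generate_landscape(
        n_ligands=300, n_clusters=4, n_strong_clusters=2, seed=7
    )


@pytest.fixture(scope="session")
def linear_problem():
    """A noiseless linear ΔG map: recoverable ground truth for the model."""
    rng = np.random.default_rng(42)
    n, d = 500, 8
    X = rng.standard_normal((n, d))
    w = rng.standard_normal(d)
    y = X @ w - 10.0
    ids = [f"lin_{i:04d}" for i in range(n)]
    block = FeatureBlock(
        "latent", X, [f"z{j}" for j in range(d)], ids
    )
    records = [
        AffinityRecord(i, float(v), source="synthetic")
        for i, v in zip(ids, y)
    ]
    return block, records, y
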