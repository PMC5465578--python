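import numpy as np
import pytest

from ddisyn.profiles import FeatureIndex, ProfileMatrix
from ddisyn.synthetic import WorldConfig, default_rules, generate_world


@pytest.fixture(scope="session")
def recovery_world():
    """Noise-free single-rule world: 200 drugs, 300 proteins (1,200 features)."""
    rules = default_rules(n_rules=1, n_proteins=300)
    return generate_world(
        WorldConfig(n_drugs=200, n_proteins=300, causal_rules=rules, seed=42)
    )


@pytest.fixture(scope="session")
def small_world():
    """Two-rule world small enough for end-to-end CLI runs."""
    return generate_world(
        WorldConfig(n_drugs=60, n_proteins=60, background_density=0.05, seed=5)
    )


@pytest.fixture()
def tiny_matrix():
    """Hand-sized profile matrix over two proteins (8 features)."""
    rng = np.random.default_rng(11)
    index = FeatureIndex(
        [(p, c) for p in ("PA", "PB") for c in ("binding", "inhibition", "activation", "catalysis")]
    )
    matrix = rng.random((12, 8)) < 0.4
    matrix[0] = False  # keep one all-zero row for edge cases
    return ProfileMatrix([f"d{i}" for i in range(12)], index, matrix)
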