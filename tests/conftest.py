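import numpy as np
import pytest

from ratiometric import ExpressionMatrix, FixtureSpec, MeasureConfig, generate_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140331)


@pytest.fixture(scope="session")
def small_matrix(rng):
    """20 positive, non-constant genes over 24 samples (lognormal)."""
    n_genes, n_samples = 20, 24
    values = np.exp(rng.normal(np.log(50.0), 0.5, (n_genes, n_samples)))
    return ExpressionMatrix(
        gene_ids=tuple(f"G{i:02d}" for i in range(n_genes)),
        sample_ids=tuple(f"S{j:02d}" for j in range(n_samples)),
        values=values,
    )


@pytest.fixture(scope="session")
def mini_panel():
    """Reduced planted-pair panel: quick but structurally complete."""
    spec = FixtureSpec(
        n_samples=100,
        n_ratiometric=10,
        n_wide=10,
        n_two_regime=10,
        n_independent=60,
        seed=7,
    )
    matrix, truth = generate_fixture(spec)
    return matrix, truth


@pytest.fixture(scope="session")
def default_config():
    return MeasureConfig()
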