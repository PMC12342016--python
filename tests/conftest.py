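import numpy as np
import pytest

import paretoscope as ps


@pytest.fixture(scope="session")
def tetra_truth():
    """Default synthetic tetrahedron cohort (four archetypes, 10:1 SNR)."""
    return ps.generate(ps.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def tetra_pca(tetra_truth):
    return ps.fit_pca(tetra_truth.expression, 8)


@pytest.fixture(scope="session")
def tetra_fit(tetra_pca):
    return ps.fit_simplex(tetra_pca.scores, 4, n_restarts=10, seed=0)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(42)
    vals = np.abs(rng.normal(10, 4, size=(12, 6)))
    return ps.ExpressionMatrix(
        values=vals,
        sample_ids=[f"s{i}" for i in range(12)],
        gene_ids=[f"g{j}" for j in range(6)],
    )
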