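import numpy as np
import pytest

from mcist import ExpressionMatrix, SpatialCoords, simulate_layered_tissue, SyntheticParams


@pytest.fixture(scope="session")
def blobs3():
    """Three isotropic Gaussian blobs: 60 spots, 40 genes, separation 8 sigma."""
    rng = np.random.default_rng(0)
    centers = rng.normal(0, 1, (3, 40))
    centers = 8.0 * centers / np.linalg.norm(centers[0] - centers[1])
    labels = np.repeat([0, 1, 2], 20)
    pts = centers[labels] + rng.normal(0, 1.0, (60, 40))
    x = ExpressionMatrix(
        pts.T - pts.min(), [f"g{i}" for i in range(40)], [f"s{i}" for i in range(60)]
    )
    return x, labels


@pytest.fixture(scope="session")
def small_tissue():
    """Fast layered-tissue fixture for pipeline tests: 10 x 12 grid, 3 domains."""
    params = SyntheticParams(
        grid_w=10, grid_h=12, n_domains=3, n_genes=60, markers_per_domain=8,
        log_fc=1.5,
    )
    return simulate_layered_tissue(params, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_expression(rng):
    vals = rng.poisson(5.0, size=(30, 25)).astype(float)
    return ExpressionMatrix(
        vals, [f"g{i}" for i in range(30)], [f"s{i}" for i in range(25)]
    )


@pytest.fixture()
def grid_coords():
    xy = np.array([[i % 5, i // 5] for i in range(25)], dtype=float)
    return SpatialCoords(xy, [f"s{i}" for i in range(25)])
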