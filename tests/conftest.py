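import numpy as np
import pandas as pd
import pytest

from curvae import manifolds as mf
from curvae import model as M
from curvae import simulate as sim


@pytest.fixture(scope="session")
def h2() -> mf.CurvatureSpace:
    return mf.hyperbolic(2, K=-2.0)


@pytest.fixture(scope="session")
def small_fixture():
    """Canonical simulation fixture (1500 cells x 400 genes)."""
    counts, genes, truth, cfg = sim.fixture_small(0)
    return counts, genes, truth, cfg


def random_hyperbolic_points(rng, space, n, scale=1.0):
    """Random manifold points through the exponential map at the origin."""
    v = rng.standard_normal((n, space.d)) * scale
    return np.asarray(mf.tangent_lift(v, space))


def random_tangents_at(rng, space, base, scale=1.0):
    """Random tangent vectors at given base points (transport from origin)."""
    n = base.shape[0]
    vt = rng.standard_normal((n, space.d)) * scale
    v = np.concatenate([np.zeros((n, 1)), vt], axis=1)
    origin = np.broadcast_to(space.origin, base.shape)
    return np.asarray(mf.parallel_transport(origin, base, v, space, check=False))


def _train_two_component(counts, genes, signal_space, signal_dist, epochs,
                         seed=0, rest_dim=5, batch=None):
    from curvae.training import TrainConfig, train

    X = counts.toarray().astype(float)
    part = M.GenePartition(
        [("signal", np.flatnonzero(genes["is_marker"])), ("rest", None)],
        X.shape[1])
    specs = [M.LatentSpec("signal", signal_space, signal_dist),
             M.LatentSpec("rest", mf.euclidean(rest_dim), "normal")]
    bd = M.CellBatchDesign(batch)
    model = M.DecomposedVAE(part, specs, bd)
    model, hist = train(model, X, batch, TrainConfig(epochs=epochs, seed=seed),
                        np.random.default_rng(seed))
    return model, X, hist


@pytest.fixture(scope="session")
def trained_gradient():
    """Model trained on the linear-gradient (zonation-like) fixture."""
    counts, genes, truth, cfg = sim.fixture_gradient(0)
    model, X, _ = _train_two_component(counts, genes, mf.euclidean(2),
                                       "normal", epochs=120)
    return model, X, genes, truth


@pytest.fixture(scope="session")
def trained_spiked():
    """Model trained on the two-condition spiked fixture."""
    counts, genes, truth = sim.fixture_spiked(0)
    model, X, _ = _train_two_component(counts, genes, mf.euclidean(4),
                                       "normal", epochs=150)
    return model, X, genes, truth


@pytest.fixture
def tiny_model():
    """A small 2-component model on 30 genes for fast forward passes."""
    from curvae.training import initialize

    rng = np.random.default_rng(0)
    part = M.GenePartition([("cycle", np.arange(8)), ("rest", None)], 30)
    specs = [
        M.LatentSpec("cycle", mf.hyperbolic(2, -2.0), "rown"),
        M.LatentSpec("rest", mf.euclidean(4), "normal"),
    ]
    bd = M.CellBatchDesign(pd.DataFrame({"batch": ["a", "b"] * 8}))
    model = M.DecomposedVAE(part, specs, bd)
    initialize(model, rng)
    X = rng.poisson(3.0, size=(16, 30)).astype(float)
    return model, X, bd.covariates
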