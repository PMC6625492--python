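import numpy as np
import pandas as pd
import pytest

import solvoptim as sv


@pytest.fixture(scope="session")
def small_library():
    """A 40-solvent synthetic library with hidden factor scores."""
    lib, scores = sv.gen_library(40, seed=101)
    return lib, scores


@pytest.fixture(scope="session")
def library_459():
    """Full-size synthetic library matching the curated-table dimensions."""
    lib, _ = sv.gen_library(459, seed=202)
    return lib


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_profile():
    """Asymmetric two-peak profile on a non-uniform grid."""
    grid = np.sort(np.random.default_rng(7).uniform(-0.025, 0.025, size=180))
    grid[0], grid[-1] = -0.025, 0.025
    dens = np.exp(-0.5 * ((grid - 0.004) / 0.006) ** 2) + 0.4 * np.exp(
        -0.5 * ((grid + 0.014) / 0.003) ** 2
    )
    return sv.SigmaProfile(grid, dens)


@pytest.fixture(scope="session")
def fitted_toy_gp():
    """GP with fixed hyperparameters on a 3-point toy set (raw units)."""
    X = np.array([[0.0, 0.0], [1.0, 0.5], [0.3, -1.0]])
    y = np.array([1.0, -0.5, 0.7])
    cfg = sv.GPConfig(
        optimize=False,
        normalize=False,
        lengthscales=np.array([0.8, 1.3]),
        signal_variance=1.2,
        noise_variance=0.05,
    )
    return sv.fit_gp(X, y, cfg, seed=0), X, y


@pytest.fixture(scope="session")
def campaign_setup():
    """Small campaign: library, oracle, initial experiments, fitted state."""
    lib, _ = sv.gen_library(30, seed=11)
    oracle = sv.make_oracle(lib, seed=12)
    pca = sv.fit_pca(lib, sv.PCA_DESCRIPTORS, k=4)
    rng = np.random.default_rng(13)
    init = [str(s) for s in rng.choice(lib.ids, size=8, replace=False)]
    rows = [
        {"solvent_id": s, **dict(zip(("conversion", "de"), oracle.query(s)))}
        for s in init
    ]
    state = sv.CampaignState(
        library=lib,
        conv_spec=sv.feature_spec(3, pca),
        de_spec=sv.feature_spec(3, pca),
        experiments=pd.DataFrame(rows),
        gp_config=sv.GPConfig(n_restarts=3),
    )
    state.refit(seed=14)
    return lib, oracle, state
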