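import numpy as np
import pytest

import cfopt
from cfopt.surrogate import ModelSpec


@pytest.fixture(scope="session")
def pb_space():
    return cfopt.load_fixture("pb_factors")


@pytest.fixture(scope="session")
def pb_runs():
    return cfopt.load_fixture("pb_runs")


@pytest.fixture(scope="session")
def pb_design(pb_space, pb_runs):
    coded = np.round(pb_runs.coded_matrix(pb_space))
    return cfopt.PBDesign(coded, tuple(range(1, len(pb_runs) + 1)))


@pytest.fixture(scope="session")
def pb_fit(pb_design, pb_runs, pb_space):
    return cfopt.fit_first_order(
        pb_design, pb_runs.responses, alpha=0.05, factor_names=pb_space.names
    )


@pytest.fixture(scope="session")
def default_oracle():
    return cfopt.make_oracle(seed=11)


@pytest.fixture
def cheap_registry():
    """Fast stand-in zoo for loop/search plumbing tests."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel
    from sklearn.linear_model import Ridge
    from sklearn.neighbors import KNeighborsRegressor

    return [
        ModelSpec("ridge", Ridge(), {"alpha": [0.1, 1.0]}),
        ModelSpec("knn", KNeighborsRegressor(), {"n_neighbors": [3, 5]}),
        ModelSpec(
            "gaussian-process",
            GaussianProcessRegressor(
                kernel=Matern(length_scale=1.0, nu=2.5) + WhiteKernel(1e-2),
                normalize_y=True,
                random_state=0,
            ),
            {"alpha": [1e-10]},
        ),
    ]
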