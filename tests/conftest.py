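import numpy as np
import pandas as pd
import pytest

from tweediemix import ModelParams, validate_and_index
from tweediemix.simulator import random_design, simulate_tmcdre


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_table(I=2, J=2, n=2, y=None, treatment=None):
    """Small deterministic long-format table for validation tests."""
    rows = []
    k = 0
    for i in range(I):
        for j in range(J):
            for _ in range(n):
                rows.append(
                    {
                        "cluster": f"c{i}",
                        "subcluster": f"s{j}",
                        "y": y[k] if y is not None else float(k % 3),
                        "treatment": (treatment[k] if treatment is not None else float(i % 2)),
                        "age": 10.0 + j,
                        "months": float(k),
                    }
                )
                k += 1
    return pd.DataFrame(rows)


LEVELS = {"treatment": "cluster", "age": "subcluster", "months": "observation"}


@pytest.fixture
def small_data():
    return validate_and_index(make_table(), LEVELS, add_intercept=True)


@pytest.fixture
def small_params():
    return ModelParams(
        beta1=np.array([0.2]),
        beta2=np.array([0.01]),
        beta3=np.array([-0.5, 0.05]),
        sigma2=0.3,
        tau2=0.5,
        rho2=0.8,
        p=1.5,
    )


def random_instance(seed, **kwargs):
    """Random small simulated instance: (MultilevelData, ModelParams).

    Retries draws whose random design happens to be unidentifiable (e.g. a
    binary cluster covariate constant across the sampled clusters).
    """
    rng = np.random.default_rng(seed)
    for _ in range(50):
        design = random_design(rng, **kwargs)
        try:
            sim = simulate_tmcdre(design, seed=int(rng.integers(2**31)))
        except ValueError:
            continue
        return sim.data, sim.params
    raise RuntimeError("could not draw an identifiable random instance")


@pytest.fixture
def instance_factory():
    return random_instance


def mc_draws(data, params, R, rng):
    """Vectorized replicate draws (U, V, Y) on a fixed design.

    Returns arrays of shape (R, I), (R, M), (R, N) following the same
    hierarchy as the simulator, drawn in bulk for Monte Carlo moment tests.
    """
    from tweediemix.moments import mean_components
    from tweediemix.simulator import sample_gamma_mean_disp, sample_tweedie_cp

    m = mean_components(data, params)
    I, M, N = data.n_clusters, data.n_subclusters, data.n_obs
    U = np.maximum(sample_gamma_mean_disp(np.tile(m.mu_i, (R, 1)), params.sigma2, rng), 1e-300)
    Usub = U[:, data.sub_cluster]
    V = np.maximum(sample_gamma_mean_disp(m.mu_ij[None, :] * Usub, params.tau2 / Usub, rng), 1e-300)
    Vobs = V[:, data.obs_subcluster]
    Y = sample_tweedie_cp(
        m.mu_ijk[None, :] * Vobs, params.rho2 * Vobs ** (1.0 - params.p), params.p, rng
    )
    return U, V, Y
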