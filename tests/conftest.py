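import numpy as np
import pytest

from latentsna import (
    BehaviorData,
    ConnectivityData,
    ModelState,
    SamplerConfig,
    SimulationConfig,
    simulate_dataset,
)


def make_state(n, v, p=1, q=1, qp=1, seed=0, sigma2=1.0, tau2=1.0,
               Sigma=None):
    rng = np.random.default_rng(seed)
    return ModelState(
        beta=rng.standard_normal(q),
        a=rng.standard_normal(n),
        sigma2=sigma2,
        gamma=rng.standard_normal(qp),
        b=rng.standard_normal(p),
        tau2=tau2,
        Z=rng.standard_normal((n, v)),
        theta=rng.standard_normal(n),
        Sigma=np.eye(v + 1) if Sigma is None else Sigma,
    )


def make_conn(edges, covariates=None, mask=None):
    edges = np.asarray(edges, dtype=float)
    n = edges.shape[0]
    if covariates is None:
        covariates = np.ones((n, 1))
    return ConnectivityData(edges=edges, covariates=covariates, mask=mask)


def make_behav(outcomes, covariates=None, mask=None):
    outcomes = np.atleast_2d(np.asarray(outcomes, dtype=float))
    n = outcomes.shape[0]
    if covariates is None:
        covariates = np.ones((n, 1))
    return BehaviorData(outcomes=outcomes, covariates=covariates, mask=mask)


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate simulated dataset with planted signal, shared across tests."""
    cfg = SimulationConfig(n_participants=300, n_regions=10, snr=1.0,
                           signal_proportion=0.2, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    from latentsna import run_chain

    conn, behav, truth = small_dataset
    cfg = SamplerConfig(n_iterations=500, burn_in=250, seed=3,
                        store_latents=True)
    return run_chain(conn, behav, config=cfg), truth
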