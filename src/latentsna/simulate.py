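"""Synthetic data from the model's own generative process.

The generator plants a region-by-behavior cross-covariance of 0.9 on a
chosen fraction of regions (the "signal" regions), sets the matching
within-connectivity covariances among those regions to the same value, and
produces edges as bilinear products plus Gaussian noise whose variance is
1/SNR (latent variance held at 1), with behavior noise variance 0.5.
Individual intercepts are zero and the single behavior item equals theta
plus noise, so the study conditions are fully determined by
(N, V, SNR, signal proportion, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import linalg as sla

from .model import BehaviorData, ConnectivityData

_MAX_SEED = 2**31 - 1


@dataclass
class SimulationConfig:
    n_participants: int = 1000
    n_regions: int = 20
    snr: float = 1.0
    signal_proportion: float = 0.1
    cross_cov_value: float = 0.9
    behavior_noise_var: float = 0.5
    n_behavior_items: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_regions < 2:
            raise ValueError("need N >= 1 and V >= 2")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0.0 <= self.signal_proportion <= 1.0:
            raise ValueError("signal_proportion must lie in [0, 1]")
        if self.behavior_noise_var <= 0:
            raise ValueError("behavior_noise_var must be positive")


@dataclass
class SimulationTruth:
    true_Sigma: np.ndarray          # (V+1, V+1)
    signal_regions: set[int]        # 0-based indices with nonzero cross-cov
    true_sigma2: float              # edge noise variance = 1/snr
    true_tau2: float                # behavior noise variance


def build_true_sigma(
    config: SimulationConfig,
) -> tuple[np.ndarray, set[int]]:
    """Construct the true joint latent covariance for one scenario.

    Unit diagonal; round(signal_proportion * V) uniformly chosen regions get
    cross-covariance ``cross_cov_value`` with the behavior latent, and the
    within-connectivity covariances among those same regions are set to the
    same value; everything else is zero.  Raises if the result is not
    positive definite (the design errors rather than projecting).
    """
    return _build_sigma(config, np.random.default_rng(config.seed))


def _build_sigma(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, set[int]]:
    v = config.n_regions
    k = int(round(config.signal_proportion * v))
    signal = set(int(i) for i in rng.choice(v, size=k, replace=False)) \
        if k else set()
    sigma = np.eye(v + 1)
    idx = sorted(signal)
    for u in idx:
        sigma[u, v] = sigma[v, u] = config.cross_cov_value
    for a_ix in idx:
        for b_ix in idx:
            if a_ix != b_ix:
                sigma[a_ix, b_ix] = config.cross_cov_value
    try:
        sla.cholesky(sigma, lower=True)
    except sla.LinAlgError as err:
        raise ValueError(
            "true covariance not positive definite at cross_cov_value="
            f"{config.cross_cov_value}; choose a smaller value"
        ) from err
    return sigma, signal


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ConnectivityData, BehaviorData, SimulationTruth]:
    """Sample one dataset: latents from MVN(0, Sigma), bilinear edges with
    N(0, 1/snr) noise, behavior y = theta + N(0, behavior_noise_var)."""
    n, v = config.n_participants, config.n_regions
    rng = np.random.default_rng(config.seed)
    sigma, signal = _build_sigma(config, rng)

    chol = sla.cholesky(sigma, lower=True)
    latent = rng.standard_normal((n, v + 1)) @ chol.T
    z, theta = latent[:, :v], latent[:, v]

    sigma2 = 1.0 / config.snr
    noise = rng.standard_normal((n, v, v)) * np.sqrt(sigma2)
    noise = np.triu(noise, 1)
    noise = noise + noise.transpose(0, 2, 1)
    edges = np.einsum("iu,iv->iuv", z, z) + noise
    idx = np.arange(v)
    edges[:, idx, idx] = 0.0

    p = config.n_behavior_items
    eps = rng.standard_normal((n, p)) * np.sqrt(config.behavior_noise_var)
    outcomes = theta[:, None] + eps

    ones = np.ones((n, 1))
    conn = ConnectivityData(edges=edges, covariates=ones)
    behav = BehaviorData(outcomes=outcomes, covariates=ones)
    truth = SimulationTruth(
        true_Sigma=sigma,
        signal_regions=signal,
        true_sigma2=sigma2,
        true_tau2=config.behavior_noise_var,
    )
    return conn, behav, truth


def scenario_grid(base_seed: int = 0) -> list[SimulationConfig]:
    """The 24-cell factorial design:
    N in {500, 1000, 2000} x V in {20, 70} x SNR in {0.5, 1}
    x signal proportion in {0.1, 0.3}, with distinct derived seeds."""
    rng = np.random.default_rng(base_seed)
    seeds = rng.choice(_MAX_SEED, size=24, replace=False)
    configs = []
    cells = product((500, 1000, 2000), (20, 70), (0.5, 1.0), (0.1, 0.3))
    for k, (n, v, snr, prop) in enumerate(cells):
        configs.append(SimulationConfig(
            n_participants=n, n_regions=v, snr=snr,
            signal_proportion=prop, seed=int(seeds[k]),
        ))
    return configs
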