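"""Out-of-sample prediction in both directions.

Behavior from connectivity comes in two flavors: the fully Bayesian route
("theta"), where test participants ride along in the MCMC with their
outcomes treated as missing and predictions are posterior-predictive means,
and the two-stage route ("z"), where ordinary least squares of training
outcomes on the posterior-mean latent coordinates of the significant
biomarker regions supplies the prediction rule.  Connectivity from behavior
imputes each test participant's latent vector through the joint latent
distribution given theta and averages posterior-predictive edge draws.
The Average baseline predicts every test matrix by the entry-wise training
mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .biomarkers import BiomarkerReport
from .model import BehaviorData, ConnectivityData, PriorSpec
from .sampler import PosteriorSamples, SamplerConfig, run_chain


@dataclass
class SplitSpec:
    """Repeated random train/test splits of participants."""

    test_size: int = 100
    n_repeats: int = 10
    seed: int = 0
    test_ids: np.ndarray | None = None   # explicit single split, optional

    def splits(self, n: int) -> list[np.ndarray]:
        if self.test_ids is not None:
            return [np.asarray(self.test_ids, dtype=int)]
        if not 0 < self.test_size < n:
            raise ValueError(f"test_size must lie in (0, {n})")
        rng = np.random.default_rng(self.seed)
        return [
            np.sort(rng.choice(n, size=self.test_size, replace=False))
            for _ in range(self.n_repeats)
        ]


def _mask_behavior(behav: BehaviorData, test_ids: np.ndarray) -> BehaviorData:
    out = BehaviorData(
        outcomes=behav.outcomes.copy(), covariates=behav.covariates.copy(),
        item_labels=list(behav.item_labels),
        participant_ids=list(behav.participant_ids), mask=behav.mask.copy(),
    )
    out.mask[test_ids] = False
    return out


def _mask_connectivity(
    conn: ConnectivityData, test_ids: np.ndarray
) -> ConnectivityData:
    out = ConnectivityData(
        edges=conn.edges.copy(), covariates=conn.covariates.copy(),
        region_labels=list(conn.region_labels),
        participant_ids=list(conn.participant_ids), mask=conn.mask.copy(),
    )
    out.mask[test_ids] = False
    return out


def predict_behavior_theta(
    conn: ConnectivityData,
    behav: BehaviorData,
    test_ids: np.ndarray,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> tuple[np.ndarray, PosteriorSamples]:
    """Posterior-predictive outcome means for test participants whose
    outcomes are masked during the fit (connectivity observed)."""
    test_ids = np.asarray(test_ids, dtype=int)
    for i in test_ids:
        if not conn.mask[i].any():
            raise ValueError(
                f"test participant {i} has no observed edges; cannot predict"
            )
    masked = _mask_behavior(behav, test_ids)
    samples = run_chain(conn, masked, priors, config)
    return samples.y_pred_mean[test_ids], samples


def predict_behavior_z(
    samples: PosteriorSamples,
    report: BiomarkerReport,
    behav: BehaviorData,
    test_ids: np.ndarray,
) -> np.ndarray:
    """Two-stage prediction: OLS of training outcomes on the posterior-mean
    latent coordinates of the significant regions, applied to test rows.

    With no significant region the training outcome mean is returned for
    every test participant, with a warning.
    """
    test_ids = np.asarray(test_ids, dtype=int)
    n = samples.Z_mean.shape[0]
    train_ids = np.setdiff1d(np.arange(n), test_ids)
    y_train = behav.outcomes[train_ids].mean(axis=1)   # univariate summary
    sig = np.nonzero(report.significant)[0]
    if sig.size == 0:
        warnings.warn(
            "no significant biomarker regions; predicting the training mean",
            stacklevel=2,
        )
        return np.full(test_ids.shape[0], float(y_train.mean()))
    x_train = samples.Z_mean[np.ix_(train_ids, sig)]
    x_test = samples.Z_mean[np.ix_(test_ids, sig)]
    design = np.column_stack([np.ones(len(train_ids)), x_train])
    coef, *_ = np.linalg.lstsq(design, y_train, rcond=None)
    return np.column_stack([np.ones(len(test_ids)), x_test]) @ coef


def predict_connectivity(
    conn: ConnectivityData,
    behav: BehaviorData,
    test_ids: np.ndarray,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> tuple[np.ndarray, PosteriorSamples]:
    """Posterior-predictive connectivity means for test participants whose
    edges are all masked (behavior observed); the test latent vector is
    imputed from the joint latent distribution given theta."""
    test_ids = np.asarray(test_ids, dtype=int)
    for i in test_ids:
        if not behav.mask[i].any():
            raise ValueError(
                f"test participant {i} has no observed behavior; cannot predict"
            )
    masked = _mask_connectivity(conn, test_ids)
    samples = run_chain(masked, behav, priors, config)
    pred = np.stack([samples.x_pred_mean[int(i)] for i in test_ids])
    return pred, samples


def restrict_to_regions(
    matrices: np.ndarray, report: BiomarkerReport, k: int
) -> tuple[np.ndarray, list[str]]:
    """Subgraph of predicted matrices on the top-k biomarker regions."""
    top = report.top_regions(k)
    labels = [report.region_labels[i] for i in top]
    sub = matrices[..., top, :][..., :, top]
    return sub, labels


def average_baseline(conn_train: ConnectivityData) -> np.ndarray:
    """Entry-wise training-mean connectivity matrix."""
    if conn_train.n_participants < 1:
        raise ValueError("need at least one training participant")
    return conn_train.edges.mean(axis=0)


def prediction_correlation(
    predicted: np.ndarray, observed: np.ndarray
) -> float:
    """Pearson correlation; matrices are vectorized over u < v entries."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed shapes differ")
    if predicted.ndim >= 2 and predicted.shape[-1] == predicted.shape[-2]:
        v = predicted.shape[-1]
        iu = np.triu_indices(v, k=1)
        predicted = predicted[..., iu[0], iu[1]].ravel()
        observed = observed[..., iu[0], iu[1]].ravel()
    else:
        predicted = predicted.ravel()
        observed = observed.ravel()
    if predicted.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(observed))):
        raise ValueError("non-finite values in correlation input")
    if predicted.std() == 0 or observed.std() == 0:
        warnings.warn("zero variance in correlation input; returning NaN",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])
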