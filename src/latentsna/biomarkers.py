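"""Region-level biomarker decisions from posterior draws.

A region is called a biomarker when the central 95% credible interval of
its cross-covariance with the behavior latent excludes zero.  No
multiplicity correction is applied across regions: decisions are per-region
credible intervals, by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampler import PosteriorSamples
from .simulate import SimulationTruth


@dataclass
class BiomarkerReport:
    region_labels: list[str]
    posterior_mean: np.ndarray      # (V,)
    ci_low: np.ndarray              # (V,)
    ci_high: np.ndarray             # (V,)
    significant: np.ndarray         # (V,) bool
    level: float = 0.95
    n_draws: int = 0

    def top_regions(self, k: int) -> list[int]:
        """Indices of the k regions with largest |posterior mean|."""
        order = np.argsort(-np.abs(self.posterior_mean))
        return [int(i) for i in order[:k]]


def summarize_covariances(
    samples: PosteriorSamples, level: float = 0.95
) -> BiomarkerReport:
    """Posterior mean, central credible interval and zero-exclusion flag per
    region, from the retained cross-covariance draws."""
    draws = np.asarray(samples.cross_cov, dtype=float)
    if draws.shape[0] < 100:
        raise ValueError(
            f"need at least 100 retained draws, got {draws.shape[0]}"
        )
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0, method="linear")
    hi = np.quantile(draws, 1.0 - alpha, axis=0, method="linear")
    mean = draws.mean(axis=0)
    sig = (lo > 0) | (hi < 0)
    v = draws.shape[1]
    labels = [str(u + 1) for u in range(v)]
    return BiomarkerReport(
        region_labels=labels, posterior_mean=mean, ci_low=lo, ci_high=hi,
        significant=sig, level=level, n_draws=draws.shape[0],
    )


def power_specificity(
    report: BiomarkerReport, truth: SimulationTruth
) -> tuple[float, float]:
    """Fraction of true signal regions flagged (power) and of true null
    regions not flagged (specificity); NaN when a denominator is empty."""
    v = len(report.posterior_mean)
    if truth.true_Sigma.shape[0] - 1 != v:
        raise ValueError(
            f"report has {v} regions but truth has "
            f"{truth.true_Sigma.shape[0] - 1}"
        )
    signal = np.zeros(v, dtype=bool)
    signal[sorted(truth.signal_regions)] = True
    flagged = np.asarray(report.significant, dtype=bool)
    n_sig = int(signal.sum())
    n_null = v - n_sig
    power = float(flagged[signal].sum() / n_sig) if n_sig else float("nan")
    spec = float((~flagged[~signal]).sum() / n_null) if n_null else float("nan")
    return power, spec
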