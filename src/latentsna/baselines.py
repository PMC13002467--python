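"""Edge-based comparison methods: CPM, L1-penalized selection, CCA selection.

All three operate on the same vectorized edge representation (columns are
u < v edges in row-major order), so benchmark comparisons against the joint
model are seed-matched on identical inputs.  Region-level flags for the
edge-level methods (CPM, L1) mark a region as selected when at least one of
its incident edges is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import CCA
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV

from .model import ConnectivityData


@dataclass
class EdgeFeatureMatrix:
    """N x M matrix of vectorized u < v edges with a column -> (u, v) map."""

    features: np.ndarray                 # (N, M)
    index_map: list[tuple[int, int]]     # column -> (u, v), 0-based
    n_regions: int

    def column_of(self, u: int, v: int) -> int:
        if u > v:
            u, v = v, u
        return self.index_map.index((u, v))


def edge_features(conn: ConnectivityData) -> EdgeFeatureMatrix:
    v = conn.n_regions
    iu = np.triu_indices(v, k=1)
    feats = conn.edges[:, iu[0], iu[1]]
    index_map = [(int(a), int(b)) for a, b in zip(*iu)]
    return EdgeFeatureMatrix(features=feats, index_map=index_map, n_regions=v)


def regions_from_edges(
    selected_edges: np.ndarray, index_map: list[tuple[int, int]], v: int
) -> set[int]:
    """A region is flagged when any incident edge is selected."""
    flagged: set[int] = set()
    for col in np.nonzero(np.asarray(selected_edges, dtype=bool))[0]:
        u, w = index_map[col]
        flagged.add(u)
        flagged.add(w)
    return flagged


def cpm_fit_predict(
    train: EdgeFeatureMatrix,
    y_train: np.ndarray,
    test: EdgeFeatureMatrix,
    p_threshold: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Connectome-based predictive modeling.

    Each edge is correlated with the training outcome; edges with two-sided
    p below the threshold form positive and negative sets; per-participant
    summary scores (sums over each set) enter a linear model fitted on
    training data and applied to the test matrix.  Returns (test
    predictions, boolean selected-edge vector).
    """
    x = np.asarray(train.features, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, m = x.shape
    if n <= 10:
        raise ValueError("CPM needs more than 10 training participants")
    if y.std() == 0:
        raise ValueError("constant training outcome; correlations undefined")

    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    selected = p < p_threshold
    pos = selected & (r > 0)
    neg = selected & (r < 0)
    if not selected.any():
        warnings.warn("no edge passed the CPM threshold; predicting the "
                      "training mean", stacklevel=2)
        return np.full(test.features.shape[0], y.mean()), selected

    cols = [np.ones(n)]
    test_cols = [np.ones(test.features.shape[0])]
    if pos.any():
        cols.append(x[:, pos].sum(axis=1))
        test_cols.append(test.features[:, pos].sum(axis=1))
    if neg.any():
        cols.append(x[:, neg].sum(axis=1))
        test_cols.append(test.features[:, neg].sum(axis=1))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    preds = np.column_stack(test_cols) @ coef
    return preds, selected


def lasso_select(
    train: EdgeFeatureMatrix,
    y_train: np.ndarray,
    cv: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Boolean selected-edge vector from L1-penalized regression with the
    penalty minimizing cv-fold cross-validated mean squared error."""
    x = np.asarray(train.features, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if x.shape[0] < 20:
        raise ValueError("L1 selection needs at least 20 training participants")
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant edge columns",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = LassoCV(cv=cv, random_state=seed, alphas=60,
                      max_iter=5000).fit(x[:, keep], y)
    selected = np.zeros(x.shape[1], dtype=bool)
    selected[np.nonzero(keep)[0]] = fit.coef_ != 0
    return selected


def cca_select(
    train: EdgeFeatureMatrix,
    y_train: np.ndarray,
    true_signal_proportion: float,
) -> set[int]:
    """Regions with the top round(proportion * V) aggregated absolute
    first-canonical-vector loadings (max over incident edges).

    When the edge block is rank deficient (more edges than participants) it
    is first reduced by principal directions and loadings are mapped back.
    """
    x = np.asarray(train.features, dtype=float)
    y = np.atleast_2d(np.asarray(y_train, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    n, m = x.shape
    v = train.n_regions

    if m >= n:
        n_comp = min(n - 1, m)
        pca = PCA(n_components=n_comp)
        xr = pca.fit_transform(x)
        back = pca.components_
    else:
        xr = x
        back = np.eye(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cca = CCA(n_components=1, max_iter=1000).fit(xr, y)
    w = cca.x_weights_[:, 0]
    edge_loadings = np.abs(back.T @ w)

    region_score = np.zeros(v)
    for col, (u, w_ix) in enumerate(train.index_map):
        load = edge_loadings[col]
        region_score[u] = max(region_score[u], load)
        region_score[w_ix] = max(region_score[w_ix], load)
    k = int(round(true_signal_proportion * v))
    order = np.argsort(-region_score)
    return set(int(i) for i in order[:k])


def _detection_rates(
    flagged: set[int], signal: set[int], v: int
) -> tuple[float, float]:
    nulls = set(range(v)) - signal
    power = len(flagged & signal) / len(signal) if signal else float("nan")
    spec = len(nulls - flagged) / len(nulls) if nulls else float("nan")
    return power, spec


def detection_benchmark(
    sim_config,
    sampler_config=None,
    methods: tuple[str, ...] = ("latentsna", "cpm", "lasso", "cca"),
    n_replicates: int = 1,
    cpm_p_threshold: float = 0.01,
):
    """Seed-matched power/specificity comparison on simulated scenarios.

    Every method sees the identical simulated dataset per replicate; the
    joint model's flags come from 95% credible-interval zero exclusion, the
    baselines' flags from their own selection rules mapped to regions.
    Returns a pandas DataFrame with one row per (replicate, method).
    """
    import pandas as pd

    from .biomarkers import power_specificity, summarize_covariances
    from .sampler import SamplerConfig, run_chain
    from .simulate import SimulationConfig, simulate_dataset

    rows = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_participants=sim_config.n_participants,
            n_regions=sim_config.n_regions,
            snr=sim_config.snr,
            signal_proportion=sim_config.signal_proportion,
            cross_cov_value=sim_config.cross_cov_value,
            behavior_noise_var=sim_config.behavior_noise_var,
            seed=(sim_config.seed + 7919 * rep) % (2**31 - 1),
        )
        conn, behav, truth = simulate_dataset(cfg)
        feats = edge_features(conn)
        y = behav.outcomes[:, 0]
        v = cfg.n_regions

        if "latentsna" in methods:
            scfg = sampler_config or SamplerConfig(
                n_iterations=600, burn_in=200, seed=cfg.seed,
            )
            samples = run_chain(conn, behav, config=scfg)
            report = summarize_covariances(samples)
            power, spec = power_specificity(report, truth)
            rows.append((rep, "latentsna", power, spec))
        if "cpm" in methods:
            _, selected = cpm_fit_predict(
                feats, y, feats, p_threshold=cpm_p_threshold
            )
            flagged = regions_from_edges(selected, feats.index_map, v)
            power, spec = _detection_rates(flagged, truth.signal_regions, v)
            rows.append((rep, "cpm", power, spec))
        if "lasso" in methods:
            selected = lasso_select(feats, y, seed=cfg.seed)
            flagged = regions_from_edges(selected, feats.index_map, v)
            power, spec = _detection_rates(flagged, truth.signal_regions, v)
            rows.append((rep, "lasso", power, spec))
        if "cca" in methods:
            flagged = cca_select(feats, y, cfg.signal_proportion)
            power, spec = _detection_rates(flagged, truth.signal_regions, v)
            rows.append((rep, "cca", power, spec))
    return pd.DataFrame(
        rows, columns=["replicate", "method", "power", "specificity"]
    )
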