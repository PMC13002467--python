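"""Generative model core: domain types, means, densities, edge standardization.

The model couples a symmetric bilinear latent-space network model for
per-participant brain connectivity with a Rasch-type measurement model for
multivariate behavior.  For participant ``i`` and regions ``u < v``::

    x[u,v,i] = w_i' beta + a_i + z[u,i] * z[v,i] + e,   e ~ N(0, sigma2)
    y[i,p]   = h_i' gamma + b_p + theta_i + eps,        eps ~ N(0, tau2)

and the per-participant latent vector ``(z_i, theta_i)`` is jointly
multivariate normal with mean zero and covariance ``Sigma`` whose
off-diagonal block ``Lambda_ztheta`` (region-by-behavior cross-covariance)
carries the biomarker signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ConnectivityData:
    """N symmetric V x V connectivity matrices plus participant covariates.

    ``edges[i]`` is symmetric on off-diagonal entries; the diagonal is never
    modeled nor read.  ``mask[i, u, v]`` is True where the edge is observed;
    missingness is carried by the mask, never by NaN.  ``covariates`` is the
    N x Q design matrix W whose first column is identically one.
    """

    edges: np.ndarray              # (N, V, V) float
    covariates: np.ndarray         # (N, Q) float, first column ones
    region_labels: list[str] = field(default_factory=list)
    participant_ids: list[str] = field(default_factory=list)
    mask: np.ndarray | None = None  # (N, V, V) bool, True = observed

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 3 or self.edges.shape[1] != self.edges.shape[2]:
            raise ValueError(
                f"edges must be (N, V, V); got shape {self.edges.shape}"
            )
        n, v = self.edges.shape[0], self.edges.shape[1]
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != n:
            raise ValueError(
                f"covariates rows ({self.covariates.shape[0]}) != N ({n})"
            )
        if not np.all(self.covariates[:, 0] == 1.0):
            raise ValueError("first covariate column must be identically 1")
        if self.mask is None:
            self.mask = np.ones((n, v, v), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.edges.shape:
                raise ValueError("mask shape must match edges shape")
        # diagonal never modeled
        idx = np.arange(v)
        self.mask[:, idx, idx] = False
        if not self.region_labels:
            self.region_labels = [str(u + 1) for u in range(v)]
        if not self.participant_ids:
            self.participant_ids = [str(i + 1) for i in range(n)]
        obs = self.edges[self.mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError("non-finite edge values among observed entries")
        sym_err = np.abs(
            np.where(self.mask, self.edges, 0.0)
            - np.where(self.mask, self.edges, 0.0).transpose(0, 2, 1)
        )
        if sym_err.size and sym_err.max() > 1e-8:
            raise ValueError("participant edge matrices are not symmetric")

    @property
    def n_participants(self) -> int:
        return self.edges.shape[0]

    @property
    def n_regions(self) -> int:
        return self.edges.shape[1]


@dataclass
class BehaviorData:
    """N x P behavior outcome matrix plus covariates H (first column ones)."""

    outcomes: np.ndarray            # (N, P)
    covariates: np.ndarray          # (N, Q')
    item_labels: list[str] = field(default_factory=list)
    participant_ids: list[str] = field(default_factory=list)
    mask: np.ndarray | None = None  # (N, P) bool, True = observed

    def __post_init__(self) -> None:
        self.outcomes = np.atleast_2d(np.asarray(self.outcomes, dtype=float))
        n, p = self.outcomes.shape
        if p < 1:
            raise ValueError("need at least one behavior item")
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != n:
            raise ValueError(
                f"covariate rows ({self.covariates.shape[0]}) != N ({n})"
            )
        if not np.all(self.covariates[:, 0] == 1.0):
            raise ValueError("first covariate column must be identically 1")
        if self.mask is None:
            self.mask = np.ones((n, p), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.outcomes.shape:
                raise ValueError("mask shape must match outcomes shape")
        obs = self.outcomes[self.mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError("non-finite outcome values among observed entries")
        if not self.item_labels:
            self.item_labels = [f"item{p_ + 1}" for p_ in range(p)]
        if not self.participant_ids:
            self.participant_ids = [str(i + 1) for i in range(n)]

    @property
    def n_participants(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_items(self) -> int:
        return self.outcomes.shape[1]


@dataclass
class PriorSpec:
    """Hyperparameters of the conjugate prior system.

    Regression coefficients get MVN(0, I); intercepts a_i, b_p get N(0, 1);
    the noise precisions 1/sigma2 and 1/tau2 get gamma(1/2, 1/2); the joint
    latent covariance Sigma gets inverse-Wishart with identity scale S0 and
    degrees of freedom m0 = V + D + 2 (D = 1), which makes the prior mean of
    Sigma the identity.
    """

    sigma_inv_shape: float = 0.5
    sigma_inv_rate: float = 0.5
    tau_inv_shape: float = 0.5
    tau_inv_rate: float = 0.5
    intercept_sd: float = 1.0
    latent_dim: int = 1

    def __post_init__(self) -> None:
        for name in ("sigma_inv_shape", "sigma_inv_rate",
                     "tau_inv_shape", "tau_inv_rate", "intercept_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.latent_dim != 1:
            raise ValueError("only D = 1 behavior latent dimension is supported")

    def beta_mean(self, q: int) -> np.ndarray:
        return np.zeros(q)

    def beta_cov(self, q: int) -> np.ndarray:
        return np.eye(q)

    def wishart_scale(self, v: int) -> np.ndarray:
        return np.eye(v + self.latent_dim)

    def wishart_df(self, v: int) -> int:
        return v + self.latent_dim + 2


@dataclass
class ModelState:
    """All parameter values of one Gibbs iteration."""

    beta: np.ndarray     # (Q,)
    a: np.ndarray        # (N,)
    sigma2: float
    gamma: np.ndarray    # (Q',)
    b: np.ndarray        # (P,)
    tau2: float
    Z: np.ndarray        # (N, V)
    theta: np.ndarray    # (N,)
    Sigma: np.ndarray    # (V+1, V+1)

    def copy(self) -> "ModelState":
        return ModelState(
            beta=self.beta.copy(), a=self.a.copy(), sigma2=float(self.sigma2),
            gamma=self.gamma.copy(), b=self.b.copy(), tau2=float(self.tau2),
            Z=self.Z.copy(), theta=self.theta.copy(), Sigma=self.Sigma.copy(),
        )

    def validate(self) -> None:
        if self.sigma2 <= 0 or self.tau2 <= 0:
            raise ValueError("sigma2 and tau2 must be strictly positive")
        _cholesky_pd(self.Sigma, "Sigma")


@dataclass
class PrecisionPartition:
    """Blocks of Sigma^{-1}: Qz (V x V), Qtz (1 x V), Qt (scalar)."""

    Qz: np.ndarray
    Qtz: np.ndarray
    Qt: float

    def assemble(self) -> np.ndarray:
        v = self.Qz.shape[0]
        q = np.empty((v + 1, v + 1))
        q[:v, :v] = self.Qz
        q[v, :v] = self.Qtz.ravel()
        q[:v, v] = self.Qtz.ravel()
        q[v, v] = self.Qt
        return q


# --------------------------------------------------------------------------
# Core operations
# --------------------------------------------------------------------------


def _cholesky_pd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    try:
        return sla.cholesky(mat, lower=True)
    except sla.LinAlgError as err:
        cond = np.linalg.cond(mat)
        raise ValueError(
            f"{name} is not positive definite (condition number {cond:.3e})"
        ) from err


def connectivity_mean(
    state: ModelState, data: ConnectivityData, participant: int
) -> np.ndarray:
    """Model mean of participant's connectivity matrix.

    Entry (u, v), u != v, is ``w_i' beta + a_i + z[u,i] z[v,i]``.  Diagonal
    entries are set to 0 and carry no meaning.
    """
    n, v = data.n_participants, data.n_regions
    if not 0 <= participant < n:
        raise IndexError(f"participant {participant} out of range [0, {n})")
    if state.Z.shape != (n, v):
        raise ValueError(
            f"state Z shape {state.Z.shape} does not match data (N={n}, V={v})"
        )
    if state.beta.shape[0] != data.covariates.shape[1]:
        raise ValueError(
            f"beta length {state.beta.shape[0]} != covariate count "
            f"{data.covariates.shape[1]}"
        )
    z = state.Z[participant]
    base = float(data.covariates[participant] @ state.beta) + float(
        state.a[participant]
    )
    mean = base + np.outer(z, z)
    np.fill_diagonal(mean, 0.0)
    return mean


def behavior_mean(
    state: ModelState, data: BehaviorData, participant: int
) -> np.ndarray:
    """Model mean of participant's behavior vector: h_i' gamma + b_p + theta_i."""
    n, p = data.n_participants, data.n_items
    if not 0 <= participant < n:
        raise IndexError(f"participant {participant} out of range [0, {n})")
    if state.b.shape[0] != p:
        raise ValueError(
            f"item intercept length {state.b.shape[0]} != item count {p}"
        )
    if state.gamma.shape[0] != data.covariates.shape[1]:
        raise ValueError(
            f"gamma length {state.gamma.shape[0]} != covariate count "
            f"{data.covariates.shape[1]}"
        )
    return (
        float(data.covariates[participant] @ state.gamma)
        + state.b
        + float(state.theta[participant])
    )


def edge_residuals(state: ModelState, conn: ConnectivityData) -> np.ndarray:
    """(N, V, V) residuals x - w'beta - a - zz' with diagonal zeroed."""
    base = conn.covariates @ state.beta + state.a           # (N,)
    bilinear = np.einsum("iu,iv->iuv", state.Z, state.Z)
    resid = conn.edges - base[:, None, None] - bilinear
    resid = np.where(conn.mask, resid, 0.0)
    return resid


def behavior_residuals(state: ModelState, behav: BehaviorData) -> np.ndarray:
    """(N, P) residuals y - h'gamma - b - theta, zeroed on missing entries."""
    mean = (behav.covariates @ state.gamma)[:, None] + state.b[None, :] \
        + state.theta[:, None]
    resid = behav.outcomes - mean
    return np.where(behav.mask, resid, 0.0)


def joint_log_density(
    state: ModelState, conn: ConnectivityData, behav: BehaviorData
) -> float:
    """Log of the joint density: edge likelihood + item likelihood + latent prior.

    Edge and item sums run over observed entries only (u < v for edges); the
    prior term is the MVN(0, Sigma) log-density of each row (z_i, theta_i).
    """
    chol = _cholesky_pd(state.Sigma, "Sigma")
    n, v = conn.n_participants, conn.n_regions

    resid = edge_residuals(state, conn)
    triu = np.triu(np.ones((v, v), dtype=bool), k=1)
    obs = conn.mask & triu[None, :, :]
    n_edges = int(obs.sum())
    sse = float((resid[obs] ** 2).sum())
    ll_edges = -0.5 * n_edges * np.log(2 * np.pi * state.sigma2) \
        - 0.5 * sse / state.sigma2

    bres = behavior_residuals(state, behav)
    n_items = int(behav.mask.sum())
    sse_y = float((bres[behav.mask] ** 2).sum())
    ll_items = -0.5 * n_items * np.log(2 * np.pi * state.tau2) \
        - 0.5 * sse_y / state.tau2

    latent = np.column_stack([state.Z, state.theta])        # (N, V+1)
    half = sla.solve_triangular(chol, latent.T, lower=True)
    quad = float((half ** 2).sum())
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    ll_prior = -0.5 * n * ((v + 1) * np.log(2 * np.pi) + logdet) - 0.5 * quad

    return ll_edges + ll_items + ll_prior


def partition_precision(Sigma: np.ndarray) -> PrecisionPartition:
    """Blocks of Sigma^{-1} used by the latent full conditionals."""
    Sigma = np.asarray(Sigma, dtype=float)
    chol = _cholesky_pd(Sigma, "Sigma")
    dim = Sigma.shape[0]
    q = sla.cho_solve((chol, True), np.eye(dim))
    v = dim - 1
    return PrecisionPartition(
        Qz=q[:v, :v], Qtz=q[v:, :v], Qt=float(q[v, v])
    )


def standardize_edges(data: ConnectivityData) -> ConnectivityData:
    """Z-score every edge (u, v) across participants (n-1 denominator).

    Requires N >= 2 and nonzero variance on every observed edge; symmetry is
    preserved because (u, v) and (v, u) carry identical values.
    """
    n, v = data.n_participants, data.n_regions
    if n < 2:
        raise ValueError("standardization needs at least 2 participants")
    edges = data.edges.copy()
    mean = edges.mean(axis=0)
    sd = edges.std(axis=0, ddof=1)
    triu = np.triu_indices(v, k=1)
    zero = sd[triu] == 0.0
    if np.any(zero):
        bad = [(int(triu[0][k]) + 1, int(triu[1][k]) + 1)
               for k in np.nonzero(zero)[0]]
        raise ValueError(f"zero-variance edges (1-based u,v pairs): {bad}")
    idx = np.arange(v)
    sd[idx, idx] = 1.0  # diagonal untouched / unused
    out = (edges - mean[None]) / sd[None]
    out[:, idx, idx] = 0.0
    return ConnectivityData(
        edges=out,
        covariates=data.covariates.copy(),
        region_labels=list(data.region_labels),
        participant_ids=list(data.participant_ids),
        mask=data.mask.copy(),
    )
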