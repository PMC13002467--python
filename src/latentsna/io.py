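"""Readers and writers: edge lists, behavior tables, fit artifacts, configs.

Connectivity travels as long-format delimited text with header
``participant_id,region_u,region_v,value`` (1-based region labels, u < v
rows); behavior and covariates as one row per participant with
``participant_id`` first.  Fits persist as an ``.npz`` array container plus
a JSON manifest carrying the schema version, seed and config echo.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomarkers import BiomarkerReport
from .model import BehaviorData, ConnectivityData, ModelState
from .sampler import PosteriorSamples, SamplerConfig
from .simulate import SimulationConfig

SCHEMA_VERSION = 1

_SAMPLER_KEYS = {
    "n_iterations", "burn_in", "thinning", "n_starts", "seed",
    "store_latents", "region_marginal_prior",
}
_SIM_KEYS = {
    "n_participants", "n_regions", "snr", "signal_proportion",
    "cross_cov_value", "behavior_noise_var", "n_behavior_items", "seed",
}


# --------------------------------------------------------------------------
# Tabular readers/writers
# --------------------------------------------------------------------------


def read_connectivity(path: str | Path) -> ConnectivityData:
    """Read a long-format edge list into symmetric per-participant matrices.

    Duplicate (u, v)/(v, u) rows must agree within 1e-9; participants keep
    first-encountered order; region labels are 1-based integers externally
    and 0-based indices internally.  Edges never mentioned for a participant
    are flagged missing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["participant_id", "region_u", "region_v", "value"]
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"{path}: header must start with {required}, got "
            f"{list(df.columns[:4])}"
        )
    if df.empty:
        raise ValueError(f"{path}: no edge rows")
    try:
        ru = df["region_u"].astype(int).to_numpy()
        rv = df["region_v"].astype(int).to_numpy()
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: region labels must be integers") from err
    if (ru < 1).any() or (rv < 1).any():
        bad = int(np.nonzero((ru < 1) | (rv < 1))[0][0]) + 2
        raise ValueError(f"{path}: line {bad}: region labels are 1-based")
    v = int(max(ru.max(), rv.max()))
    pids = list(dict.fromkeys(df["participant_id"].astype(str)))
    pid_ix = {p: i for i, p in enumerate(pids)}
    n = len(pids)
    edges = np.zeros((n, v, v))
    mask = np.zeros((n, v, v), dtype=bool)
    vals = df["value"].to_numpy(dtype=float)
    rows_pid = df["participant_id"].astype(str).to_numpy()
    for line, (pid, u, w, val) in enumerate(zip(rows_pid, ru, rv, vals)):
        if u == w:
            raise ValueError(
                f"{path}: line {line + 2}: self-edge ({u},{w}) not allowed"
            )
        i = pid_ix[pid]
        a, b = u - 1, w - 1
        if mask[i, a, b] and abs(edges[i, a, b] - val) > 1e-9:
            raise ValueError(
                f"{path}: line {line + 2}: conflicting duplicate for "
                f"participant {pid} edge ({u},{w})"
            )
        edges[i, a, b] = edges[i, b, a] = val
        mask[i, a, b] = mask[i, b, a] = True
    if not np.all(np.isfinite(vals)):
        bad = int(np.nonzero(~np.isfinite(vals))[0][0]) + 2
        raise ValueError(f"{path}: line {bad}: non-finite edge value")
    return ConnectivityData(
        edges=edges, covariates=np.ones((n, 1)),
        region_labels=[str(u + 1) for u in range(v)],
        participant_ids=pids, mask=mask,
    )


def write_connectivity(conn: ConnectivityData, path: str | Path) -> None:
    v = conn.n_regions
    iu = np.triu_indices(v, k=1)
    rows = []
    for i, pid in enumerate(conn.participant_ids):
        for a, b in zip(*iu):
            if conn.mask[i, a, b]:
                rows.append((pid, a + 1, b + 1, conn.edges[i, a, b]))
    pd.DataFrame(
        rows, columns=["participant_id", "region_u", "region_v", "value"]
    ).to_csv(path, index=False)


def read_behavior(
    path: str | Path, conn: ConnectivityData | None = None
) -> BehaviorData:
    """Read a behavior table; when paired connectivity is given, rows are
    realigned to its participant order and unmatched IDs are an error."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "participant_id":
        raise ValueError(
            f"{path}: first column must be participant_id, got {df.columns[0]}"
        )
    df["participant_id"] = df["participant_id"].astype(str)
    if conn is not None:
        want = conn.participant_ids
        have = set(df["participant_id"])
        extra = sorted(have - set(want))
        missing = sorted(set(want) - have)
        if extra or missing:
            raise ValueError(
                f"{path}: participant mismatch with connectivity; "
                f"extra={extra}, missing={missing}"
            )
        df = df.set_index("participant_id").loc[want].reset_index()
    items = [c for c in df.columns if c != "participant_id"]
    if not items:
        raise ValueError(f"{path}: no outcome columns")
    n = len(df)
    return BehaviorData(
        outcomes=df[items].to_numpy(dtype=float),
        covariates=np.ones((n, 1)),
        item_labels=items,
        participant_ids=list(df["participant_id"]),
    )


def write_behavior(behav: BehaviorData, path: str | Path) -> None:
    df = pd.DataFrame(behav.outcomes, columns=behav.item_labels)
    df.insert(0, "participant_id", behav.participant_ids)
    df.to_csv(path, index=False)


def read_covariates(path: str | Path, participant_ids: list[str]) -> np.ndarray:
    """Covariate table aligned to an existing participant order; a leading
    column of ones is prepended."""
    df = pd.read_csv(path)
    if df.columns[0] != "participant_id":
        raise ValueError(f"{path}: first column must be participant_id")
    df["participant_id"] = df["participant_id"].astype(str)
    missing = sorted(set(participant_ids) - set(df["participant_id"]))
    if missing:
        raise ValueError(f"{path}: missing covariates for {missing}")
    df = df.set_index("participant_id").loc[participant_ids]
    mat = df.to_numpy(dtype=float)
    return np.column_stack([np.ones(len(participant_ids)), mat])


def write_report(report: BiomarkerReport, path: str | Path) -> None:
    pd.DataFrame({
        "region_label": report.region_labels,
        "posterior_mean": report.posterior_mean,
        "ci_low": report.ci_low,
        "ci_high": report.ci_high,
        "significant": report.significant.astype(int),
    }).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Fit persistence
# --------------------------------------------------------------------------


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_fit(
    state: ModelState,
    samples: PosteriorSamples,
    out_dir: str | Path,
    config: SamplerConfig | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {
        "cross_cov": samples.cross_cov,
        "lambda_theta": samples.lambda_theta,
        "sigma2_draws": samples.sigma2_draws,
        "tau2_draws": samples.tau2_draws,
        "beta_draws": samples.beta_draws,
        "gamma_draws": samples.gamma_draws,
        "Z_mean": samples.Z_mean,
        "theta_mean": samples.theta_mean,
        "a_mean": samples.a_mean,
        "b_mean": samples.b_mean,
        "y_pred_mean": samples.y_pred_mean,
        "state_beta": state.beta,
        "state_a": state.a,
        "state_gamma": state.gamma,
        "state_b": state.b,
        "state_Z": state.Z,
        "state_theta": state.theta,
        "state_Sigma": state.Sigma,
        "state_scalars": np.array([state.sigma2, state.tau2]),
    }
    if samples.Z_draws is not None:
        arrays["Z_draws"] = samples.Z_draws
        arrays["theta_draws"] = samples.theta_draws
    np.savez(out / "chains.npz", **arrays)
    cfg = {
        "n_iterations": samples.n_iterations,
        "burn_in": samples.burn_in,
        "thinning": samples.thinning,
        "seed": samples.seed,
    }
    if config is not None:
        cfg.update({
            "n_starts": config.n_starts,
            "store_latents": config.store_latents,
            "region_marginal_prior": config.region_marginal_prior,
        })
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "start_scores": samples.start_scores,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_fit(out_dir: str | Path) -> tuple[ModelState, PosteriorSamples]:
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"manifest schema version {manifest.get('schema_version')} "
            f"!= supported {SCHEMA_VERSION}"
        )
    with np.load(out / "chains.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    scalars = arrays["state_scalars"]
    state = ModelState(
        beta=arrays["state_beta"], a=arrays["state_a"],
        sigma2=float(scalars[0]), gamma=arrays["state_gamma"],
        b=arrays["state_b"], tau2=float(scalars[1]),
        Z=arrays["state_Z"], theta=arrays["state_theta"],
        Sigma=arrays["state_Sigma"],
    )
    cfg = manifest["config"]
    samples = PosteriorSamples(
        cross_cov=arrays["cross_cov"],
        lambda_theta=arrays["lambda_theta"],
        sigma2_draws=arrays["sigma2_draws"],
        tau2_draws=arrays["tau2_draws"],
        beta_draws=arrays["beta_draws"],
        gamma_draws=arrays["gamma_draws"],
        Z_mean=arrays["Z_mean"],
        theta_mean=arrays["theta_mean"],
        a_mean=arrays["a_mean"],
        b_mean=arrays["b_mean"],
        y_pred_mean=arrays["y_pred_mean"],
        x_pred_mean={},
        n_iterations=int(cfg["n_iterations"]),
        burn_in=int(cfg["burn_in"]),
        thinning=int(cfg["thinning"]),
        seed=int(cfg["seed"]),
        final_state=state,
        Z_draws=arrays.get("Z_draws"),
        theta_draws=arrays.get("theta_draws"),
        start_scores=list(manifest.get("start_scores", [])),
    )
    return state, samples


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


def load_run_config(path: str | Path) -> dict:
    """Strict YAML/JSON run configuration: unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {
        "connectivity", "behavior", "covariates", "output", "log_level",
        "sampler", "simulation", "prediction", "grid", "standardize",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "sampler" in raw:
        bad = set(raw["sampler"]) - _SAMPLER_KEYS
        if bad:
            raise ValueError(f"{path}: unknown sampler keys {sorted(bad)}")
    if "simulation" in raw:
        bad = set(raw["simulation"]) - _SIM_KEYS
        if bad:
            raise ValueError(f"{path}: unknown simulation keys {sorted(bad)}")
    return raw


def sampler_config_from_dict(d: dict) -> SamplerConfig:
    return SamplerConfig(**{k: d[k] for k in d if k in _SAMPLER_KEYS})


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(**{k: d[k] for k in d if k in _SIM_KEYS})
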