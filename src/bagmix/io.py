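"""File formats and run manifests.

Datasets travel as plain CSV (columns ``subject_id, occasion, y``, then
the ungrouped covariate columns, then the grouped columns) with a JSON or
YAML group-map sidecar::

    {"ungrouped": ["x1", "x2"],
     "groups": {"G1": ["g1a", "g1b", "g1c"], ...}}

Hyperparameter/chain configuration is YAML.  Draws are written one CSV
per chain with columns named ``state{s}.alpha{l}``,
``state{s}.betaG{j}.{c}``, ``state{s}.sigma2``, ``state{s}.lambda2{l}``,
``state{s}.gamma2{j}``, ``q{s}`` (1-based), one row per iteration;
assignments go to a parallel integer CSV.  Every CLI run directory gets a
``manifest.json`` capturing config, seeds, input digests and versions so
the run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gibbs import ChainConfig, ChainResult
from .model import Dataset, GroupStructure, Hyperparameters

_HYPER_KEYS = ("a", "b", "a_lambda", "b_lambda", "a_gamma", "b_gamma")


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration."""


def load_config(path: str | Path) -> Hyperparameters:
    """Load and validate a hyperparameter YAML file.

    Unknown keys are rejected; every value must be a positive number.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of hyperparameters")
    unknown = set(raw) - set(_HYPER_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    missing = set(_HYPER_KEYS) - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing keys {sorted(missing)}")
    vals = {}
    for key in _HYPER_KEYS:
        v = raw[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"{path}: field {key} must be a number, got {v!r}")
        if not v > 0:
            raise ConfigError(f"{path}: field {key} must be > 0, got {v}")
        vals[key] = float(v)
    return Hyperparameters(**vals)


def write_config(hyper: Hyperparameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(hyper), sort_keys=False))


# ---------------------------------------------------------------------------
# dataset CSV + group map

def load_group_map(path: str | Path) -> tuple[list[str], dict[str, list[str]]]:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ConfigError(f"{path}: expected keys 'ungrouped' and 'groups'")
    ungrouped = list(raw.get("ungrouped", []))
    groups = {str(k): list(v) for k, v in raw["groups"].items()}
    if not groups:
        raise ConfigError(f"{path}: at least one group is required")
    return ungrouped, groups


def read_dataset(csv_path: str | Path, groups_path: str | Path) -> Dataset:
    """Read a dataset CSV plus its group-map sidecar.

    Rows are sorted by (subject_id, occasion); every subject must be
    observed the same number of times (the model assumes balanced
    panels).
    """
    df = pd.read_csv(csv_path)
    for col in ("subject_id", "occasion", "y"):
        if col not in df.columns:
            raise ConfigError(f"{csv_path}: missing required column {col!r}")
    ungrouped, groups = load_group_map(groups_path)
    for name in ungrouped + [c for cols in groups.values() for c in cols]:
        if name not in df.columns:
            raise ConfigError(f"group map references absent column {name!r}")
    df = df.sort_values(["subject_id", "occasion"], kind="stable")
    counts = df.groupby("subject_id").size()
    if counts.nunique() != 1:
        raise ConfigError(
            f"{csv_path}: ragged panel — occasions per subject range "
            f"{counts.min()}..{counts.max()}"
        )
    N, T = len(counts), int(counts.iloc[0])
    structure = GroupStructure(
        L=len(ungrouped), group_sizes=tuple(len(cols) for cols in groups.values())
    )
    grouped_cols = [c for cols in groups.values() for c in cols]
    true_states = (
        df["true_state"].to_numpy() if "true_state" in df.columns else None
    )
    return Dataset(
        y=df["y"].to_numpy(),
        X_alpha=df[ungrouped].to_numpy() if ungrouped else np.empty((N * T, 0)),
        X_beta=df[grouped_cols].to_numpy(),
        structure=structure,
        N=N,
        T=T,
        true_states=true_states,
    )


def write_dataset(
    dataset: Dataset,
    csv_path: str | Path,
    groups_path: str | Path,
    ungrouped_names: list[str] | None = None,
    group_names: dict[str, list[str]] | None = None,
) -> None:
    """Write a dataset and its group map; default column names are
    ``a1..aL`` and ``G{j}_{c}``."""
    st = dataset.structure
    if ungrouped_names is None:
        ungrouped_names = [f"a{l + 1}" for l in range(st.L)]
    if group_names is None:
        group_names = {
            f"G{j + 1}": [f"G{j + 1}_{c + 1}" for c in range(pj)]
            for j, pj in enumerate(st.group_sizes)
        }
    cols = {
        "subject_id": np.repeat(np.arange(1, dataset.N + 1), dataset.T),
        "occasion": np.tile(np.arange(1, dataset.T + 1), dataset.N),
        "y": dataset.y,
    }
    for l, name in enumerate(ungrouped_names):
        cols[name] = dataset.X_alpha[:, l]
    flat = [c for cs in group_names.values() for c in cs]
    for c, name in enumerate(flat):
        cols[name] = dataset.X_beta[:, c]
    if dataset.true_states is not None:
        cols["true_state"] = dataset.true_states
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    Path(groups_path).write_text(
        json.dumps({"ungrouped": ungrouped_names, "groups": group_names}, indent=1)
    )


# ---------------------------------------------------------------------------
# draws

def draws_frame(chain: ChainResult, group_sizes: tuple[int, ...]) -> pd.DataFrame:
    """One row per iteration, named columns per parameter."""
    S, L = chain.S, chain.alpha.shape[2]
    cols: dict[str, np.ndarray] = {}
    for s in range(S):
        tag = f"state{s + 1}"
        for l in range(L):
            cols[f"{tag}.alpha{l + 1}"] = chain.alpha[:, s, l]
        offset = 0
        for j, pj in enumerate(group_sizes):
            for c in range(pj):
                cols[f"{tag}.betaG{j + 1}.{c + 1}"] = chain.beta[:, s, offset + c]
            offset += pj
        cols[f"{tag}.sigma2"] = chain.sigma2[:, s]
        for l in range(L):
            cols[f"{tag}.lambda2{l + 1}"] = chain.lambda2[:, s, l]
        for j in range(len(group_sizes)):
            cols[f"{tag}.gamma2{j + 1}"] = chain.gamma2[:, s, j]
    for s in range(S):
        cols[f"q{s + 1}"] = chain.q[:, s]
    return pd.DataFrame(cols)


def write_chain(
    chain: ChainResult,
    out_dir: str | Path,
    group_sizes: tuple[int, ...],
    chain_id: int = 1,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    draws_frame(chain, group_sizes).to_csv(out / f"chain{chain_id}_draws.csv", index=False)
    pd.DataFrame(chain.assignments).to_csv(
        out / f"chain{chain_id}_assignments.csv", index=False
    )


def read_chain(run_dir: str | Path, chain_id: int = 1) -> tuple[ChainResult, tuple[int, ...]]:
    """Reconstruct a ChainResult from a fit run directory.

    Shapes are inferred from the draw-file column names; the chain config
    comes from the run's manifest.  Latent tau draws are not persisted and
    are restored as ones (they are nuisance scales, unused by selection
    and diagnostics).  Returns (chain, group_sizes).
    """
    run = Path(run_dir)
    df = pd.read_csv(run / f"chain{chain_id}_draws.csv")
    manifest = json.loads((run / "manifest.json").read_text())
    cfg_raw = manifest["config"]
    cfg = ChainConfig(**{k: cfg_raw[k] for k in (
        "n_iter", "burn_in", "n_chains", "seed", "init_mode", "q_update")})
    S = max(int(c.removeprefix("q")) for c in df.columns if c.startswith("q"))
    alpha_cols = sorted(
        c for c in df.columns if c.startswith("state1.alpha")
    )
    L = len(alpha_cols)
    beta_cols = [c for c in df.columns if c.startswith("state1.betaG")]
    J = max(int(c.split(".")[1].removeprefix("betaG")) for c in beta_cols)
    group_sizes = tuple(
        sum(1 for c in beta_cols if c.split(".")[1] == f"betaG{j + 1}")
        for j in range(J)
    )
    n_iter = len(df)
    p = sum(group_sizes)

    alpha = np.empty((n_iter, S, L))
    beta = np.empty((n_iter, S, p))
    sigma2 = np.empty((n_iter, S))
    lambda2 = np.empty((n_iter, S, L))
    gamma2 = np.empty((n_iter, S, J))
    q = np.empty((n_iter, S))
    for s in range(S):
        tag = f"state{s + 1}"
        for l in range(L):
            alpha[:, s, l] = df[f"{tag}.alpha{l + 1}"]
            lambda2[:, s, l] = df[f"{tag}.lambda2{l + 1}"]
        offset = 0
        for j, pj in enumerate(group_sizes):
            for c in range(pj):
                beta[:, s, offset + c] = df[f"{tag}.betaG{j + 1}.{c + 1}"]
            offset += pj
            gamma2[:, s, j] = df[f"{tag}.gamma2{j + 1}"]
        sigma2[:, s] = df[f"{tag}.sigma2"]
        q[:, s] = df[f"q{s + 1}"]
    assign_path = run / f"chain{chain_id}_assignments.csv"
    if assign_path.exists():
        assignments = pd.read_csv(assign_path).to_numpy(dtype=np.int16)
    else:
        assignments = np.ones((n_iter, 1), dtype=np.int16)
    chain = ChainResult(
        alpha=alpha,
        beta=beta,
        sigma2=sigma2,
        lambda2=lambda2,
        gamma2=gamma2,
        tau_alpha2=np.ones((n_iter, S, L)),
        tau_group2=np.ones((n_iter, S, J)),
        q=q,
        assignments=assignments,
        config=cfg,
    )
    return chain, group_sizes


# ---------------------------------------------------------------------------
# manifest

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int,
    inputs: list[str | Path] = (),
    warnings: list[str] = (),
) -> Path:
    """Write manifest.json capturing everything needed to reproduce a run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "versions": {
            "bagmix": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "warnings": list(warnings),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def chain_config_dict(cfg: ChainConfig) -> dict:
    return asdict(cfg)
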