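"""Reading relations / positions / features and archiving fitted results.

Relations are read from dense CSV, sparse (i, j, value) triplet CSV, or
Matrix Market files; observation kind and directedness come from an
optional ``<file>.meta.json`` sidecar or from explicit arguments.
Fitted sample sets round-trip through a JSON archive so downstream
metrics are exactly reproducible from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .core import (
    Assignment,
    ComponentParams,
    EntityGeometry,
    GriddedHyper,
    ModelState,
    Relation,
    SampleSet,
    SomaDepthModel,
)

SCHEMA_VERSION = 1

DENSE_CSV = "dense_csv"
SPARSE_TRIPLET = "sparse_triplet"
MATRIX_MARKET = "matrix_market"


def _sidecar_meta(path: Path) -> dict:
    meta = Path(str(path) + ".meta.json")
    if meta.exists():
        return json.loads(meta.read_text())
    return {}


def read_relation(path, format: str = DENSE_CSV, obs_kind=None, directed=None) -> Relation:
    """Read a square relation matrix; sparse formats treat absences as 0."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _sidecar_meta(path)
    obs_kind = obs_kind or meta.get("obs_kind", "bernoulli")
    directed = meta.get("directed", False) if directed is None else directed
    if format == DENSE_CSV:
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append([float(x) for x in line.split(",")])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-numeric cell ({exc})") from None
                if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                    raise ValueError(f"{path}:{ln}: ragged row "
                                     f"({len(rows[-1])} cells, expected {len(rows[0])})")
        if not rows:
            raise ValueError(f"{path}: empty relation file")
        matrix = np.asarray(rows)
    elif format == SPARSE_TRIPLET:
        df = pd.read_csv(path, header=None, names=["i", "j", "v"])
        if df.empty:
            raise ValueError(f"{path}: empty relation file")
        n = int(max(df["i"].max(), df["j"].max())) + 1
        matrix = np.zeros((n, n))
        matrix[df["i"].astype(int), df["j"].astype(int)] = df["v"].values
        if not directed:
            matrix = np.maximum(matrix, matrix.T)
    elif format == MATRIX_MARKET:
        matrix = mmread(path)
        if hasattr(matrix, "todense"):
            matrix = matrix.todense()
        matrix = np.asarray(matrix)
    else:
        raise ValueError(f"unknown relation format {format!r}")
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path}: relation is not square: {matrix.shape}")
    if obs_kind == "bernoulli":
        matrix = (matrix > 0).astype(np.int64)
    else:
        matrix = np.round(matrix).astype(np.int64)
    rel = Relation(matrix, obs_kind=obs_kind, directed=directed)
    bad = rel.validate()
    if bad:
        raise ValueError(f"{path}: {'; '.join(bad)}")
    return rel


def read_positions(path) -> EntityGeometry:
    """Tabular positions with an ``id`` column; rows are joined on id."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate entity id {dup!r}")
    df = df.sort_values("id").reset_index(drop=True)
    if not np.array_equal(df["id"].values, np.arange(len(df))):
        raise ValueError(f"{path}: ids must be exactly 0..N-1")
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    if not coord_cols:
        raise ValueError(f"{path}: no coordinate columns (x, y, z)")
    return EntityGeometry(df[coord_cols].values.astype(float))


def read_features(depth_path=None, profile_path=None, n=None):
    """Read per-entity soma depths and/or synapse depth profiles.

    Depth file: CSV with columns id, depth (one row per entity; missing
    entities get NaN).  Profile file: CSV with columns id, depth, one
    row per synapse.  Returns (depths array or None, profiles list or
    None).
    """
    depths = None
    profiles = None
    if depth_path is not None:
        df = pd.read_csv(depth_path)
        if df["id"].duplicated().any():
            raise ValueError(f"{depth_path}: duplicate entity id")
        size = n or int(df["id"].max()) + 1
        depths = np.full(size, np.nan)
        depths[df["id"].astype(int).values] = df["depth"].values
    if profile_path is not None:
        df = pd.read_csv(profile_path)
        size = n or int(df["id"].max()) + 1
        profiles = [np.array([])] * size
        for ent, grp in df.groupby("id"):
            profiles[int(ent)] = grp["depth"].values.astype(float)
    return depths, profiles


# ---------------------------------------------------------------------------
# results archive
# ---------------------------------------------------------------------------

def _hyper_to_dict(h: GriddedHyper) -> dict:
    return {
        "grids": {k: v.tolist() for k, v in h.grids.items()},
        "idx": dict(h.idx),
        "fixed": dict(h.fixed),
    }


def _hyper_from_dict(d: dict) -> GriddedHyper:
    return GriddedHyper({k: np.asarray(v) for k, v in d["grids"].items()},
                        idx=dict(d["idx"]), fixed=dict(d["fixed"]))


def state_to_dict(state: ModelState) -> dict:
    d = {
        "labels": state.assignment.labels.tolist(),
        "params": [{k: v.tolist() for k, v in cp.tables.items()}
                   for cp in state.component_params],
        "hyper": [_hyper_to_dict(h) for h in state.hyper],
        "alpha": _hyper_to_dict(state.alpha),
        "temperature": state.temperature,
        "rng_seed": int(state.rng_seed),
    }
    if state.soma is not None:
        d["soma"] = {
            "depths": state.soma.depths.tolist(),
            "mu_hp": state.soma.mu_hp, "kappa_hp": state.soma.kappa_hp,
            "sigma2_hp": state.soma.sigma2_hp, "nu_hp": state.soma.nu_hp,
        }
    if state.synapse is not None:
        d["synapse"] = {
            "means": state.synapse.means.tolist(),
            "weights": state.synapse.weights.tolist(),
            "sigma2": state.synapse.sigma2,
        }
    return d


def state_from_dict(d: dict) -> ModelState:
    soma = None
    if "soma" in d:
        s = d["soma"]
        soma = SomaDepthModel(np.asarray(s["depths"]), s["mu_hp"], s["kappa_hp"],
                              s["sigma2_hp"], s["nu_hp"])
    synapse = None
    if "synapse" in d:
        from .core import SynapseProfileModel
        s = d["synapse"]
        synapse = SynapseProfileModel([], np.asarray(s["means"]),
                                      np.asarray(s["weights"]), s["sigma2"])
    return ModelState(
        assignment=Assignment(np.asarray(d["labels"])),
        component_params=[ComponentParams({k: np.asarray(v) for k, v in cp.items()})
                          for cp in d["params"]],
        hyper=[_hyper_from_dict(h) for h in d["hyper"]],
        alpha=_hyper_from_dict(d["alpha"]),
        soma=soma,
        synapse=synapse,
        temperature=d["temperature"],
        rng_seed=d.get("rng_seed", 0),
    )


def write_results(sample_set: SampleSet, coassignment=None, metrics=None,
                  path="results", config=None) -> Path:
    """Write a versioned JSON archive of a fitted sample set."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "states": [state_to_dict(s) for s in sample_set.samples],
        "log_scores": [float(x) for x in sample_set.log_scores],
        "chain_ids": [int(c) for c in sample_set.chain_ids],
        "metrics": metrics or {},
        "config": config or {},
    }
    (path / "results.json").write_text(json.dumps(payload))
    if coassignment is not None:
        np.savetxt(path / "coassignment.csv", np.asarray(coassignment),
                   delimiter=",", fmt="%.6f")
    return path


def load_results(path):
    """Reload an archive; returns (SampleSet, coassignment or None, metrics)."""
    path = Path(path)
    payload = json.loads((path / "results.json").read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported results schema version {version!r}")
    samples = SampleSet(
        samples=[state_from_dict(d) for d in payload["states"]],
        log_scores=payload["log_scores"],
        chain_ids=payload["chain_ids"],
    )
    co = None
    co_path = path / "coassignment.csv"
    if co_path.exists():
        co = np.loadtxt(co_path, delimiter=",")
    return samples, co, payload.get("metrics", {})


__all__ = [
    "read_relation",
    "read_positions",
    "read_features",
    "write_results",
    "load_results",
    "state_to_dict",
    "state_from_dict",
    "DENSE_CSV",
    "SPARSE_TRIPLET",
    "MATRIX_MARKET",
    "SCHEMA_VERSION",
]
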