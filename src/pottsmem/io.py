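"""File formats, run manifests and deterministic test fixtures.

Pattern sets travel as a TSV matrix (N rows x p columns of integer states
0..S) plus a JSON sidecar with the generation metadata; matrices (correlation,
distance, weights) as labeled TSV.  ``make_fixture`` builds small seeded
datasets so that every analysis is exercisable without external data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .patterns import (
    GenerationParams,
    ParentAssignment,
    ParentPatterns,
    PatternSet,
    generate,
    generate_uncorrelated,
)

__all__ = [
    "FormatError",
    "write_patterns",
    "read_patterns",
    "write_matrix",
    "read_matrix",
    "write_manifest",
    "load_run_config",
    "save_couplings",
    "load_couplings",
    "make_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = (
    "tiny-uncorrelated",
    "tiny-multiparent",
    "tiny-ultrametric",
    "toy-weights",
)

#: allowed keys of the two RunConfig blocks
_GENERATION_KEYS = {
    "N", "S", "a", "n_parents", "n_children", "f", "a_p", "zeta",
    "eps_max", "seed",
}
_NETWORK_KEYS = {"N", "S", "a", "c_m", "U", "beta", "seed"}
_EXPERIMENT_KEYS = {
    "alphas", "n_cues", "criterion_overlap", "criterion_fraction",
    "zeta_grid", "f_grid", "seed",
}


class FormatError(ValueError):
    """Malformed pattern/matrix file."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_patterns(patterns: PatternSet, path: str | Path) -> None:
    """Write states as TSV and metadata as a JSON sidecar (same stem).

    Parent patterns and the parent-child assignment, when present, are
    serialized alongside (``<stem>.parents.tsv`` / ``<stem>.assignment.tsv``)
    so that shared-parent and factor-overlap analyses survive a round trip.
    """
    path = Path(path)
    np.savetxt(path, patterns.xi, fmt="%d", delimiter="\t")
    meta = {
        "N": patterns.N,
        "S": patterns.S,
        "a": patterns.a,
        **{k: _jsonable(v) for k, v in patterns.meta.items() if k != "H_m"},
    }
    if patterns.parents is not None:
        np.savetxt(
            path.with_suffix(".parents.tsv"), patterns.parents.states,
            fmt="%d", delimiter="\t",
        )
        meta["parents_file"] = path.with_suffix(".parents.tsv").name
    if patterns.assignment is not None:
        np.savetxt(
            path.with_suffix(".assignment.tsv"),
            patterns.assignment.membership.astype(np.int8),
            fmt="%d", delimiter="\t",
        )
        meta["assignment_file"] = path.with_suffix(".assignment.tsv").name
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_patterns(path: str | Path, metadata_only: bool = False) -> PatternSet | dict:
    """Read a TSV + JSON-sidecar pattern set back, validating states.

    With ``metadata_only`` the sidecar alone is parsed (provenance queries).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("N", "S", "a"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
    if metadata_only:
        return meta
    xi = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    if xi.shape[0] != meta["N"]:
        raise FormatError(
            f"{path}: {xi.shape[0]} rows, sidecar says N={meta['N']}"
        )
    bad = np.argwhere((xi < 0) | (xi > meta["S"]))
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{path}: state {xi[r, c]} out of range 0..{meta['S']} "
            f"at row {r}, column {c}"
        )
    parents = assignment = None
    if "parents_file" in meta:
        states = np.loadtxt(
            path.parent / meta["parents_file"], dtype=np.int32,
            delimiter="\t", ndmin=2,
        )
        parents = ParentPatterns(states=states)
    if "assignment_file" in meta:
        membership = np.loadtxt(
            path.parent / meta["assignment_file"], dtype=np.int8,
            delimiter="\t", ndmin=2,
        ).astype(bool)
        assignment = ParentAssignment(membership=membership)
    return PatternSet(
        xi=xi.astype(np.int32),
        N=int(meta["N"]),
        S=int(meta["S"]),
        a=float(meta["a"]),
        meta=meta,
        parents=parents,
        assignment=assignment,
    )


def write_matrix(
    m: np.ndarray, path: str | Path, labels: list[str] | None = None
) -> None:
    labels = labels or [f"item{i}" for i in range(m.shape[0])]
    cols = labels if m.ndim == 2 and m.shape[1] == len(labels) else None
    pd.DataFrame(m, index=labels, columns=cols).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def load_run_config(path: str | Path) -> dict:
    """Parse and validate a nested run configuration (JSON or YAML).

    Recognized blocks: ``generation``, ``network``, ``experiment``; unknown
    blocks or keys are rejected so that typos fail loudly.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    allowed = {
        "generation": _GENERATION_KEYS,
        "network": _NETWORK_KEYS,
        "experiment": _EXPERIMENT_KEYS,
    }
    for block, content in cfg.items():
        if block not in allowed:
            raise FormatError(f"{path}: unknown config block {block!r}")
        unknown = set(content) - allowed[block]
        if unknown:
            raise FormatError(
                f"{path}: unknown key(s) {sorted(unknown)} in block {block!r}"
            )
    return cfg


def save_couplings(couplings, path: str | Path) -> None:
    """Persist couplings + connectivity in an HDF5 container (the one large
    binary object in a workflow)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("J", data=couplings.J, compression="gzip")
        f.create_dataset("indptr", data=couplings.conn.indptr)
        f.create_dataset("indices", data=couplings.conn.indices)
        f.attrs["N"] = couplings.conn.N
        f.attrs["c_m"] = couplings.conn.c_m
        f.attrs["S"] = couplings.S
        f.attrs["a"] = couplings.a
        f.attrs["p"] = couplings.p


def load_couplings(path: str | Path):
    import h5py

    from .network import Connectivity, Couplings

    with h5py.File(path, "r") as f:
        conn = Connectivity(
            indptr=f["indptr"][:], indices=f["indices"][:],
            N=int(f.attrs["N"]), c_m=int(f.attrs["c_m"]),
        )
        return Couplings(
            J=f["J"][:], conn=conn, S=int(f.attrs["S"]),
            a=float(f.attrs["a"]), p=int(f.attrs["p"]),
        )


def write_manifest(path: str | Path, config: dict, seeds: dict | None = None) -> None:
    """Resolved-config manifest written next to every CLI output."""
    payload = {
        "package": "pottsmem",
        "version": __version__,
        "config": _jsonable(config),
        "seeds": _jsonable(seeds or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def strict_hierarchy_distances(
    n_clusters: int = 4, cluster_size: int = 5, d_within: float = 1.0,
    d_between: float = 2.0,
) -> np.ndarray:
    """Two-level block-ultrametric distance matrix (synthetic)."""
    labels = np.repeat(np.arange(n_clusters), cluster_size)
    D = np.where(labels[:, None] == labels[None, :], d_within, d_between)
    np.fill_diagonal(D, 0.0)
    return D


def exponential_weights(
    n_items: int = 30, n_features: int = 12, rate: float = 0.08, seed: int = 7
) -> np.ndarray:
    """Synthetic nonnegative item x feature weights whose sorted feature sums
    decay exactly exponentially with the given rate."""
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.full(n_items, 5.0), size=n_features).T  # items x feat
    totals = np.exp(-rate * np.arange(1, n_features + 1))
    return shares * totals


def make_fixture(name: str, seed: int = 2024):
    """Deterministic small datasets for tests and examples.

    ``tiny-uncorrelated`` / ``tiny-multiparent``: N=100, S=3, a=0.25, p=50
    pattern sets; ``tiny-ultrametric``: a 20-item strict two-level distance
    matrix; ``toy-weights``: a 30 x 12 exponential-profile weight matrix
    (all synthetic).
    """
    if name == "tiny-uncorrelated":
        return generate_uncorrelated(
            GenerationParams(N=100, S=3, a=0.25, n_children=50, seed=seed)
        )
    if name == "tiny-multiparent":
        return generate(
            GenerationParams(
                N=100, S=3, a=0.25, n_parents=20, n_children=50, f=0.2,
                a_p=0.4, zeta=0.05, seed=seed,
            )
        )
    if name == "tiny-ultrametric":
        return strict_hierarchy_distances()
    if name == "toy-weights":
        return exponential_weights()
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
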