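"""File formats: LD matrices, variant metadata, Z-scores, groups, results.

Conventions: genomic positions and group labels are 1-based; matrices are
whitespace-delimited dense text or an ``.npz`` container with the matrix
under key ``"sigma"``; tabular files are TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .covmodels import CorrelationModel, ValidationError
from .grouping import GroupPartition, KeySelection

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_correlation_model",
    "read_zscores",
    "write_zscores",
    "write_groups",
    "write_solution_sidecar",
]


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a dense matrix from text or from an npz container (key 'sigma')."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            if "sigma" not in f:
                raise ValidationError(f"{path} holds keys {list(f.keys())}, expected 'sigma'")
            return np.asarray(f["sigma"], dtype=float)
    return np.loadtxt(path, dtype=float, ndmin=2)


def write_matrix(path: str | Path, M: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, sigma=M)
    else:
        np.savetxt(path, M, fmt="%.10g")


def read_correlation_model(
    sigma_path: str | Path, meta_path: Optional[str | Path] = None
) -> CorrelationModel:
    """Load an LD matrix with optional `id chr pos` metadata TSV."""
    sigma = read_matrix(sigma_path)
    sigma = 0.5 * (sigma + sigma.T)
    np.fill_diagonal(sigma, 1.0)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"id": str, "chr": str})
        if "pos" in meta.columns:
            meta["pos"] = meta["pos"].astype(int)
    return CorrelationModel(sigma=sigma, variant_meta=meta)


def read_zscores(
    path: str | Path, variant_meta: Optional[pd.DataFrame] = None
) -> Tuple[pd.Series, np.ndarray]:
    """Read a TSV with header ``id z`` (extra columns allowed).

    If ``variant_meta`` is given, the Z-scores are aligned to the metadata's
    variant order; ids missing on either side raise a structured error.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"id": str})
    df.columns = [c.lower() for c in df.columns]
    if "id" not in df.columns or "z" not in df.columns:
        raise ValidationError(f"{path} must have columns 'id' and 'z'")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate ids in {path}: {dups}")
    z = pd.to_numeric(df["z"], errors="coerce")
    if z.isna().any():
        bad = df.loc[z.isna(), "id"].tolist()
        raise ValidationError(f"non-numeric z values for ids: {bad}")
    if variant_meta is not None:
        order = variant_meta["id"].astype(str)
        missing = sorted(set(order) - set(df["id"]))
        extra = sorted(set(df["id"]) - set(order))
        if missing or extra:
            raise ValidationError(
                f"z-score/LD id mismatch; absent from z-scores: {missing[:10]}, "
                f"absent from LD metadata: {extra[:10]}"
            )
        df = df.set_index("id").loc[order].reset_index()
        z = df["z"].astype(float)
    return df["id"], z.to_numpy(dtype=float)


def write_zscores(path: str | Path, ids, z: np.ndarray) -> None:
    pd.DataFrame({"id": ids, "z": z}).to_csv(path, sep="\t", index=False)


def write_groups(
    path: str | Path,
    partition: GroupPartition,
    variant_meta: Optional[pd.DataFrame] = None,
    keys: Optional[KeySelection] = None,
) -> None:
    """Write `id chr pos group is_key` TSV (1-based groups)."""
    p = partition.p
    if variant_meta is None:
        variant_meta = pd.DataFrame({
            "id": [f"v{i + 1}" for i in range(p)],
            "chr": ["1"] * p,
            "pos": np.arange(1, p + 1),
        })
    is_key = np.ones(p, dtype=int)
    if keys is not None:
        is_key[:] = 0
        is_key[keys.key_indices] = 1
    out = variant_meta.copy().reset_index(drop=True)
    out["group"] = partition.assignment
    out["is_key"] = is_key
    out.to_csv(path, sep="\t", index=False)


def write_solution_sidecar(path: str | Path, solution, extra: Optional[dict] = None) -> None:
    """JSON sidecar with method, m, objective trace, slacks, and seeds."""
    lam_s, lam_d = solution.slack
    payload = {
        "method": solution.method,
        "m": solution.m,
        "objective_trace": [float(v) for v in solution.objective_trace],
        "lambda_min_S": lam_s,
        "lambda_min_D": lam_d,
        "eps_boundary": solution.eps_boundary,
    }
    if solution.gamma_equi is not None:
        payload["tau_equi"] = float(solution.gamma_equi)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
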