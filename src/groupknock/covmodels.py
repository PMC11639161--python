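"""Correlation-matrix container, regularization, and synthetic covariance families.

The knockoff constructions in this package operate on a correlation matrix
``Sigma`` describing the joint second moments of the features (in the GWAS
setting, the linkage-disequilibrium matrix of a block of variants).  This
module provides a validated container for such matrices, a ridge-style
regularizer that shifts them toward the identity until they are safely
positive definite, and generators for the five synthetic covariance families
used by the simulation harness: equicorrelated blocks, Erdős–Rényi random
covariance and precision graphs, and AR(1) chains with constant or random
adjacent correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationModel",
    "CovarianceSpec",
    "ValidationError",
    "regularize",
    "make_covariance",
    "cov_to_corr",
]

#: default lower bound imposed on the smallest eigenvalue by :func:`regularize`
DEFAULT_EPS_PD = 0.01

#: grid step for the identity-shift coefficient searched by :func:`regularize`
GAMMA_STEP = 0.01

_SYM_TOL = 1e-12


class ValidationError(ValueError):
    """Structured validation failure for user-supplied inputs."""


@dataclass(frozen=True)
class CorrelationModel:
    """A p×p correlation matrix with optional per-variant metadata.

    Parameters
    ----------
    sigma : ndarray of shape (p, p)
        Symmetric matrix with unit diagonal.
    variant_meta : DataFrame, optional
        Per-column records with columns ``id``, ``chr``, ``pos`` (1-based).
    gamma_reg : float
        Identity-shift coefficient applied by :func:`regularize` (0 if none).
    """

    sigma: np.ndarray
    variant_meta: Optional[pd.DataFrame] = None
    gamma_reg: float = 0.0

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
            raise ValidationError(f"sigma must be square, got shape {sigma.shape}")
        if not np.all(np.abs(sigma - sigma.T) <= _SYM_TOL):
            raise ValidationError("sigma is not symmetric (tolerance 1e-12)")
        if not np.all(np.abs(np.diag(sigma) - 1.0) <= _SYM_TOL):
            raise ValidationError("sigma does not have a unit diagonal (tolerance 1e-12)")
        object.__setattr__(self, "sigma", sigma)
        if self.variant_meta is not None:
            meta = self.variant_meta
            required = {"id", "chr", "pos"}
            if not required.issubset(meta.columns):
                raise ValidationError(f"variant_meta must have columns {sorted(required)}")
            if len(meta) != sigma.shape[0]:
                raise ValidationError("variant_meta length does not match sigma dimension")
            if meta["id"].duplicated().any():
                dups = meta.loc[meta["id"].duplicated(), "id"].tolist()
                raise ValidationError(f"duplicate variant ids: {dups}")

    @property
    def p(self) -> int:
        return self.sigma.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.sigma)[0])


@dataclass(frozen=True)
class CovarianceSpec:
    """Specification of one synthetic covariance family draw.

    ``kind`` selects the family:

    ``block``
        Block-diagonal with equicorrelated blocks of size ``b``; within-block
        correlation is ``rho_b`` if given, otherwise drawn per block from
        U(0.3, 0.9).
    ``er_cov``
        Erdős–Rényi sparse symmetric matrix (edge probability ``q_er``,
        weights U(0.2, 0.6) with random sign), diagonal loaded for positive
        definiteness, rescaled to correlation.
    ``er_prec``
        Same construction applied to the precision matrix, then inverted and
        rescaled.
    ``ar1``
        AR(1): Sigma_ij = rho^|i-j| with constant ``rho`` (default 0.5).
    ``ar1_corr``
        AR(1) chain with independent adjacent correlations rho_j ~ U(0.2, 0.8).
    """

    kind: str
    p: int
    seed: int = 0
    params: dict = field(default_factory=dict)

    _KINDS = ("block", "er_cov", "er_prec", "ar1", "ar1_corr")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown covariance kind {self.kind!r}; choose from {self._KINDS}")
        if self.p < 1:
            raise ValidationError("p must be a positive integer")


def cov_to_corr(M: np.ndarray) -> np.ndarray:
    """Rescale a covariance matrix to unit diagonal (correlation form)."""
    d = np.sqrt(np.diag(M))
    if np.any(d <= 0):
        raise ValidationError("matrix has non-positive diagonal; cannot rescale to correlation")
    C = M / np.outer(d, d)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def regularize(model: CorrelationModel, eps_pd: float = DEFAULT_EPS_PD) -> CorrelationModel:
    """Shift ``Sigma`` toward the identity until its smallest eigenvalue is >= eps_pd.

    Returns ``Sigma_reg = (1-gamma) Sigma + gamma I`` with gamma the smallest
    value on the grid {0, 0.01, 0.02, ...} achieving ``lambda_min >= eps_pd``.
    The shift preserves the unit diagonal exactly; gamma is recorded in the
    result's ``gamma_reg`` field (combined multiplicatively with any previous
    shift).  Idempotent: an already-compliant matrix is returned unchanged.
    """
    if not (0 < eps_pd < 1):
        raise ValidationError("eps_pd must be in (0, 1)")
    lam = model.min_eigenvalue()
    if lam >= eps_pd:
        return model
    # (1-g)*lam_min + g >= eps_pd  <=>  g >= (eps_pd - lam)/(1 - lam)
    g_exact = (eps_pd - lam) / (1.0 - lam)
    gamma = GAMMA_STEP * int(np.ceil(g_exact / GAMMA_STEP - 1e-12))
    gamma = min(gamma, 1.0)
    sigma = (1.0 - gamma) * model.sigma + gamma * np.eye(model.p)
    np.fill_diagonal(sigma, 1.0)
    total = 1.0 - (1.0 - model.gamma_reg) * (1.0 - gamma)
    return replace(model, sigma=sigma, gamma_reg=total)


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if not (-1.0 < rho < 1.0):
        raise ValidationError(f"rho must lie in (-1, 1), got {rho}")
    return rho


def _gen_block(p, rng, params):
    b = int(params.get("b", 5))
    if b < 1:
        raise ValidationError("block size b must be >= 1")
    sigma = np.zeros((p, p))
    for start in range(0, p, b):
        stop = min(start + b, p)
        k = stop - start
        if "rho_b" in params:
            rho = _check_rho(params["rho_b"])
        else:
            rho = rng.uniform(0.3, 0.9)
        blk = np.full((k, k), rho)
        np.fill_diagonal(blk, 1.0)
        sigma[start:stop, start:stop] = blk
    return sigma


def _gen_er_raw(p, rng, params):
    """Sparse symmetric ER matrix with diagonal loaded to lambda_min >= 0.1."""
    q = float(params.get("q_er", 0.1))
    if not (0.0 < q < 1.0):
        raise ValidationError(f"q_er must lie in (0, 1), got {q}")
    lo, hi = params.get("w_lo", 0.2), params.get("w_hi", 0.6)
    mask = np.triu(rng.random((p, p)) < q, k=1)
    w = rng.uniform(lo, hi, size=(p, p)) * rng.choice([-1.0, 1.0], size=(p, p))
    A = np.where(mask, w, 0.0)
    A = A + A.T
    lam = np.linalg.eigvalsh(A)[0]
    np.fill_diagonal(A, max(0.1 - lam, 0.1))
    A[np.diag_indices(p)] += 1.0  # keep well away from singular before rescale
    return A


def _gen_ar1(p, rho_vec):
    # Sigma_ij = prod of adjacent correlations between i and j
    cum = np.concatenate([[0.0], np.cumsum(np.log(np.abs(rho_vec)))]) if len(rho_vec) else np.array([0.0])
    sgn = np.concatenate([[1.0], np.cumprod(np.sign(rho_vec))]) if len(rho_vec) else np.array([1.0])
    sigma = np.exp(-np.abs(cum[:, None] - cum[None, :]))
    sigma *= np.outer(sgn, sgn)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def make_covariance(spec: CovarianceSpec) -> CorrelationModel:
    """Draw one correlation matrix from the requested synthetic family.

    Deterministic given ``spec.seed``; the output is rescaled to unit diagonal
    and passes :class:`CorrelationModel` validation (apply :func:`regularize`
    before factorization-heavy use).
    """
    rng = np.random.default_rng(spec.seed)
    p, params = spec.p, spec.params
    if spec.kind == "block":
        sigma = _gen_block(p, rng, params)
    elif spec.kind == "er_cov":
        sigma = _gen_er_raw(p, rng, params)
    elif spec.kind == "er_prec":
        prec = _gen_er_raw(p, rng, params)
        sigma = np.linalg.inv(prec)
    elif spec.kind == "ar1":
        rho = _check_rho(params.get("rho", 0.5))
        if rho == 0.0:
            sigma = np.eye(p)
        else:
            k = np.arange(p)
            sigma = rho ** np.abs(k[:, None] - k[None, :])
    elif spec.kind == "ar1_corr":
        lo, hi = params.get("rho_lo", 0.2), params.get("rho_hi", 0.8)
        for v in (lo, hi):
            _check_rho(v)
        rho_vec = rng.uniform(lo, hi, size=max(p - 1, 0))
        sigma = _gen_ar1(p, rho_vec)
    else:  # pragma: no cover - guarded in CovarianceSpec
        raise ValidationError(spec.kind)
    sigma = cov_to_corr(sigma)
    return CorrelationModel(sigma=sigma)
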