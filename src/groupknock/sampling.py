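"""Sampling second-order Gaussian group knockoffs.

Three routes are provided:

* individual-level: each standardized sample row x gets m knockoff copies
  ``x~_k = P x + eps_k`` with ``(eps_1, ..., eps_m) ~ N(0, V)`` jointly;
* ghost (summary-statistic): the same conditional law applied directly to a
  vector of marginal GWAS Z-scores, producing knockoff Z-scores without any
  individual-level data;
* group-key: knockoffs are sampled only for the key variables (on the key
  submatrix of Sigma) and the non-key knockoffs are regenerated from the
  within-group conditional regression, which is valid whenever the feature
  distribution has the group-key conditional independence property.

The conditional law follows from Gaussian conditioning on the joint
covariance G_S: ``P = I - S Sigma^-1``; V has diagonal blocks
``2S - S Sigma^-1 S`` and off-diagonal blocks ``S - S Sigma^-1 S``.  The
implied joint covariance of (X, X~_1..m) then reproduces G_S exactly, which
is enforced as a test contract.

Knockoff copies are laid out copy-major: columns [0, p) are copy 1,
[p, 2p) copy 2, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .covmodels import CorrelationModel, ValidationError
from .grouping import ConditionalRegression, KeySelection
from .solver import KnockoffSolution

__all__ = [
    "KnockoffSample",
    "conditional_knockoff_law",
    "sample_knockoffs_gaussian",
    "sample_ghost_zscores",
    "sample_knockoffs_group_key",
]

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class KnockoffSample:
    """m knockoff copies in copy-major layout, with provenance."""

    values: np.ndarray  # n x (m p) matrix, or length-(m p) vector for ghosts
    m: int
    p: int
    seed: Optional[int]
    layout: str = "copy-major"

    def copy(self, k: int) -> np.ndarray:
        """Return the k-th knockoff copy (1-based)."""
        if not (1 <= k <= self.m):
            raise ValidationError(f"copy index {k} outside 1..{self.m}")
        sl = slice((k - 1) * self.p, k * self.p)
        return self.values[..., sl]


def conditional_knockoff_law(
    sigma: np.ndarray, S: np.ndarray, m: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian law of the m knockoff copies given the originals.

    Returns (P, V) with ``X~_k | X = x  =  P x + eps_k`` and
    ``(eps_1..eps_m) ~ N(0, V)`` jointly across copies; V is mp x mp with
    diagonal blocks ``2S - S Sigma^-1 S`` and off-diagonal blocks
    ``S - S Sigma^-1 S``.  Raises if V is not PSD beyond a -1e-8 tolerance
    (infeasible (Sigma, S) pair).
    """
    p = sigma.shape[0]
    SinvS = np.linalg.solve(sigma, S)  # Sigma^-1 S; its transpose is S Sigma^-1
    P = np.eye(p) - SinvS.T
    core = S - S @ SinvS  # S - S Sigma^-1 S, symmetric
    core = 0.5 * (core + core.T)
    V = np.tile(core, (m, m))
    for k in range(m):
        V[k * p:(k + 1) * p, k * p:(k + 1) * p] = core + S
    V = 0.5 * (V + V.T)
    lam = np.linalg.eigvalsh(V)[0]
    if lam < -_PSD_TOL:
        raise ValidationError(
            f"conditional covariance V is not PSD (lambda_min = {lam:.3e}); "
            "the (Sigma, S) pair is infeasible for m copies"
        )
    return P, V


def _psd_sqrt(V: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh(V)
    w = np.clip(w, 0.0, None)
    return Q * np.sqrt(w)


def sample_knockoffs_gaussian(
    X: np.ndarray, sigma: np.ndarray, S: np.ndarray, m: int, seed: Optional[int]
) -> KnockoffSample:
    """Sample m individual-level knockoff copies for every row of X.

    Rows are treated as independent observations with covariance Sigma and
    (approximately) standardized columns.  Reproducible given ``seed``; the
    empirical second moments of (X, X~) converge to G_S.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = sigma.shape[0]
    if X.shape[1] != p:
        raise ValidationError(f"X has {X.shape[1]} columns, Sigma is {p}x{p}")
    P, V = conditional_knockoff_law(sigma, S, m)
    rng = np.random.default_rng(seed)
    root = _psd_sqrt(V)
    E = rng.standard_normal((X.shape[0], m * p)) @ root.T
    mean = X @ P.T
    values = np.tile(mean, (1, m)) + E
    return KnockoffSample(values=values, m=m, p=p, seed=seed)


def sample_ghost_zscores(
    z: np.ndarray, sigma: np.ndarray, S: np.ndarray, m: int, seed: Optional[int]
) -> KnockoffSample:
    """Sample knockoff copies of a vector of marginal Z-scores.

    Under the null-model CLT the Z-scores are N(0, Sigma), so the same
    conditional law applies: ``z~ = (P z, ..., P z) + eps`` with
    ``eps ~ N(0, V)``.
    """
    z = np.asarray(z, dtype=float).ravel()
    p = sigma.shape[0]
    if z.size != p:
        raise ValidationError(f"z has length {z.size}, Sigma is {p}x{p}")
    P, V = conditional_knockoff_law(sigma, S, m)
    rng = np.random.default_rng(seed)
    eps = _psd_sqrt(V) @ rng.standard_normal(m * p)
    values = np.tile(P @ z, m) + eps
    return KnockoffSample(values=values, m=m, p=p, seed=seed)


def sample_knockoffs_group_key(
    data: np.ndarray,
    model: CorrelationModel,
    keys: KeySelection,
    regressions: ConditionalRegression,
    solution_star: KnockoffSolution,
    m: int,
    seed: Optional[int],
) -> KnockoffSample:
    """Sample group knockoffs through the key-variable route.

    Step 1: sample m knockoff copies of the key coordinates using the solved
    S* on the key submatrix of Sigma (individual-level if ``data`` is a
    matrix, ghost Z-scores if it is a vector).  Step 2: for each copy and
    each group, regenerate the non-key coordinates from the within-group
    conditional regression, ``x~_dagger = B x~_star(group) + eta`` with
    ``eta ~ N(0, R)``, independently across copies, groups and samples.  The
    output is assembled in original index order.  When every variable is a
    key (c = 1) this reduces exactly - including the random stream - to the
    plain Gaussian sampler on the full Sigma.
    """
    data = np.asarray(data, dtype=float)
    ghost = data.ndim == 1
    key_idx = keys.key_indices
    p = model.p
    if solution_star.S.shape[0] != key_idx.size:
        raise ValidationError("solution_star was not solved on the key submatrix")
    sigma_star = model.sigma[np.ix_(key_idx, key_idx)]
    data_star = data[key_idx] if ghost else data[:, key_idx]
    if ghost:
        star = sample_ghost_zscores(data_star, sigma_star, solution_star.S, m, seed)
    else:
        star = sample_knockoffs_gaussian(data_star, sigma_star, solution_star.S, m, seed)

    if key_idx.size == p:  # c = 1: nothing to regenerate
        return KnockoffSample(values=star.values, m=m, p=p, seed=seed)

    rng = np.random.default_rng(None if seed is None else seed + 1)
    pos_in_star = {j: t for t, j in enumerate(key_idx)}
    n = 1 if ghost else data.shape[0]
    out = np.zeros((n, m * p))
    star_vals = np.atleast_2d(star.values)
    kstar = key_idx.size
    for k in range(m):
        xk_star = star_vals[:, k * kstar:(k + 1) * kstar]
        out[:, k * p + key_idx] = xk_star[:, [pos_in_star[j] for j in key_idx]]
        for s_idx, d_idx, B, R in zip(keys.star, keys.dagger, regressions.B, regressions.R):
            if d_idx.size == 0:
                continue
            cols = [pos_in_star[j] for j in s_idx]
            mean = xk_star[:, cols] @ B.T
            root = _psd_sqrt(R)
            eta = rng.standard_normal((n, d_idx.size)) @ root.T
            out[:, k * p + d_idx] = mean + eta
    values = out.ravel() if ghost else out
    return KnockoffSample(values=values, m=m, p=p, seed=seed)
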