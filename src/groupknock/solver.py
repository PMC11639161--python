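"""Optimization of the block-diagonal S matrix for second-order group knockoffs.

Given a feature correlation matrix ``Sigma`` and a partition of the features
into groups, knockoff quality is governed by the group-block-diagonal matrix
``S`` through the joint covariance ``G_S`` of the originals and their m
knockoff copies (diagonal blocks ``Sigma``, off-diagonal blocks
``Sigma - S``).  Validity requires ``S >= 0`` and ``D = ((m+1)/m) Sigma - S
>= 0``; power favors S as "large" as possible in the sense of one of three
objectives:

``sdp``
    group-size-normalized absolute deviation  sum_g |A_g|^-2 sum_{ij in A_g}
    |S_ij - Sigma_ij| (minimized);
``maxent``
    the negative log-determinant of G_S, equal up to an S-independent
    constant to  -[m logdet(S) + logdet(D)] (minimized = entropy maximized);
``mvr``
    Tr(G_S^-1) = (1/m) Tr(D^-1) + m Tr(S^-1) (minimized);
``equi``
    the one-parameter equivariant family S_g = tau Sigma_g with the largest
    feasible tau (closed form, no iteration).

The iterative solver alternates full coordinate descent over every free
entry of S with rank-1 "PCA" updates along the eigenvectors of the
block-diagonal part of Sigma, maintaining Cholesky factors of S and D under
rank-1/rank-2 updates so each step costs O(p^2).

The identities used throughout follow from the eigenstructure of G_S: with
``J`` the all-ones (m+1)x(m+1) matrix, ``G_S = J (x) (Sigma - S) + I (x) S``
has determinant ``m^p det(D) det(S)^m`` and inverse trace
``(1/m) Tr(D^-1) + m Tr(S^-1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .covmodels import CorrelationModel, ValidationError
from .grouping import GroupPartition

__all__ = [
    "SolverOptions",
    "KnockoffSolution",
    "SolverState",
    "objective",
    "assemble_gs",
    "solve_equi",
    "solve_group_knockoff",
    "feasible_interval",
    "me_coordinate_update",
    "generic_coordinate_update",
    "pca_update",
    "apply_update",
]

_METHODS = ("maxent", "mvr", "sdp", "equi")


# ---------------------------------------------------------------------------
# Cholesky rank-1 update/downdate kernels
# ---------------------------------------------------------------------------

def _chol_rank1_py(L, x, sign):
    p = L.shape[0]
    for k in range(p):
        Lkk = L[k, k]
        r2 = Lkk * Lkk + sign * x[k] * x[k]
        if r2 <= 0.0:
            return 1
        r = np.sqrt(r2)
        c = r / Lkk
        s = x[k] / Lkk
        L[k, k] = r
        if k + 1 < p:
            L[k + 1:, k] = (L[k + 1:, k] + sign * s * x[k + 1:]) / c
            x[k + 1:] = c * x[k + 1:] - s * L[k + 1:, k]
    return 0


try:  # jit the sequential kernel; the pure-numpy version is the fallback
    from numba import njit

    _chol_rank1 = njit(cache=True)(_chol_rank1_py)
    _chol_rank1(np.eye(2), np.zeros(2), 1.0)  # warm the compile cache
except Exception:  # pragma: no cover
    _chol_rank1 = _chol_rank1_py


def chol_update(L: np.ndarray, x: np.ndarray, downdate: bool = False) -> bool:
    """In-place rank-1 update (or downdate) of a lower Cholesky factor.

    Returns True on success; False if the downdate destroyed positive
    definiteness (caller should refactorize).
    """
    return _chol_rank1(L, x.copy(), -1.0 if downdate else 1.0) == 0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SolverOptions:
    """Knobs of the iterative S solver.

    ``m`` is the number of knockoff copies; ``eps_boundary`` is removed from
    both ends of every feasible interval so iterates never touch the PD
    boundary; ``alternation`` is the schedule of update phases executed per
    round (by default one full coordinate sweep then one full PCA sweep,
    back-to-back).
    """

    method: str = "maxent"
    m: int = 1
    max_sweeps: int = 100
    tol_obj: float = 1e-4
    eps_boundary: float = 1e-6
    alternation: Tuple[str, ...] = ("coord", "pca")
    seed: Optional[int] = None

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValidationError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.eps_boundary < 0:
            raise ValidationError("eps_boundary must be >= 0")
        for phase in self.alternation:
            if phase not in ("coord", "pca"):
                raise ValidationError(f"unknown alternation phase {phase!r}")


@dataclass
class KnockoffSolution:
    """A solved block-diagonal S with provenance and diagnostics."""

    S: np.ndarray
    m: int
    method: str
    partition: GroupPartition
    sigma: np.ndarray
    objective_trace: List[float] = field(default_factory=list)
    gamma_equi: Optional[float] = None
    B_whiten: Optional[np.ndarray] = None
    eps_boundary: float = 1e-6

    @property
    def D(self) -> np.ndarray:
        return ((self.m + 1) / self.m) * self.sigma - self.S

    @property
    def slack(self) -> Tuple[float, float]:
        """(lambda_min(S), lambda_min(D)) — both must be >= -1e-8."""
        return (
            float(np.linalg.eigvalsh(self.S)[0]),
            float(np.linalg.eigvalsh(self.D)[0]),
        )

    def materialize_gs(self) -> np.ndarray:
        return assemble_gs(self.sigma, self.S, self.m)


def assemble_gs(sigma: np.ndarray, S: np.ndarray, m: int) -> np.ndarray:
    """Assemble the (m+1)p x (m+1)p joint covariance of (X, X~_1..m)."""
    p = sigma.shape[0]
    G = np.tile(sigma - S, (m + 1, m + 1))
    for k in range(m + 1):
        G[k * p:(k + 1) * p, k * p:(k + 1) * p] = sigma
    return G


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def _sdp_loss(S, sigma, partition):
    loss = 0.0
    for g in partition.groups:
        blk = np.ix_(g, g)
        loss += np.abs(S[blk] - sigma[blk]).sum() / g.size**2
    return loss


def objective(
    S: np.ndarray,
    sigma: np.ndarray,
    m: int,
    method: str,
    partition: Optional[GroupPartition] = None,
) -> float:
    """Evaluate the selected loss at (S, Sigma, m).

    ``maxent`` returns -[m logdet(S) + logdet(D)], the log-determinant of
    G_S^-1 with the S-independent constant p log m dropped; ``mvr`` returns
    Tr(G_S^-1); ``sdp`` the normalized absolute deviation (requires the
    partition).  A singular S or D yields +inf.
    """
    D = ((m + 1) / m) * sigma - S
    if method == "sdp":
        if partition is None:
            raise ValidationError("sdp objective requires the group partition")
        return _sdp_loss(S, sigma, partition)
    try:
        C = np.linalg.cholesky(S)
        L = np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        return np.inf
    if method in ("maxent", "equi"):
        return -2.0 * (m * np.log(np.diag(C)).sum() + np.log(np.diag(L)).sum())
    if method == "mvr":
        Cinv = solve_triangular(C, np.eye(S.shape[0]), lower=True)
        Linv = solve_triangular(L, np.eye(S.shape[0]), lower=True)
        return m * float((Cinv**2).sum()) + (1.0 / m) * float((Linv**2).sum())
    raise ValidationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Solver state
# ---------------------------------------------------------------------------

class SolverState:
    """S, D and their Cholesky factors, maintained under low-rank updates."""

    def __init__(self, sigma: np.ndarray, partition: GroupPartition, S0: np.ndarray, m: int):
        self.sigma = sigma
        self.partition = partition
        self.m = m
        self.p = sigma.shape[0]
        self.S = S0.copy()
        self.D = ((m + 1) / m) * sigma - self.S
        self.C = np.linalg.cholesky(self.S)
        self.L = np.linalg.cholesky(self.D)
        self.group_of = partition.assignment

    # -- quadratic forms ----------------------------------------------------
    def _quads(self, F: np.ndarray, idx: Sequence[int]) -> np.ndarray:
        """Gram matrix of F^-1 e_i for i in idx, i.e. entries of (FF^t)^-1."""
        E = np.zeros((self.p, len(idx)))
        for c, i in enumerate(idx):
            E[i, c] = 1.0
        Y = solve_triangular(F, E, lower=True)
        return Y.T @ Y

    def quads_S(self, idx):
        return self._quads(self.C, idx)

    def quads_D(self, idx):
        return self._quads(self.L, idx)

    def _inv_cols(self, F: np.ndarray, idx: Sequence[int]):
        """Columns of (FF^t)^-1 at idx, plus their Gram matrix entries."""
        E = np.zeros((self.p, len(idx)))
        for c, i in enumerate(idx):
            E[i, c] = 1.0
        Y = solve_triangular(F, E, lower=True)
        Z = solve_triangular(F.T, Y, lower=False)
        return Y.T @ Y, Z.T @ Z  # (FF^t)^-1 entries, (FF^t)^-2 entries

    def quad_vec(self, F: np.ndarray, v: np.ndarray):
        y = solve_triangular(F, v, lower=True)
        z = solve_triangular(F.T, y, lower=False)
        return float(y @ y), float(z @ z)  # v'M^-1 v, v'M^-2 v

    def rebuild(self):
        self.C = np.linalg.cholesky(self.S)
        self.L = np.linalg.cholesky(self.D)

    def factor_error(self) -> float:
        return max(
            np.abs(self.C @ self.C.T - self.S).max(),
            np.abs(self.L @ self.L.T - self.D).max(),
        )


# ---------------------------------------------------------------------------
# Feasible intervals
# ---------------------------------------------------------------------------

def feasible_interval(state: SolverState, i: int, j: int) -> Tuple[float, float]:
    """The printed coordinate-descent step region for entry (i, j) of S.

    For i = j the bounds (-1/(S^-1)_jj, 1/(D^-1)_jj) are exact.  For i != j
    the bounds -2/[(S^-1)_ii + 2(S^-1)_ij + (S^-1)_jj] and
    2/[(D^-1)_ii + 2(D^-1)_ij + (D^-1)_jj] are quadratic-form relaxations of
    the true PD region; the solver additionally clamps steps to the exact
    det-root region (see :func:`exact_interval`).  Both ends are shrunk
    inward by ``eps`` by the caller.  The interval always contains 0.
    """
    if state.group_of[i] != state.group_of[j]:
        raise ValidationError("entry (i, j) lies outside the block pattern")
    if i == j:
        a = state.quads_S([j])[0, 0]
        d = state.quads_D([j])[0, 0]
        return (-1.0 / a, 1.0 / d)
    A = state.quads_S([i, j])
    Dq = state.quads_D([i, j])
    lo = -2.0 / (A[0, 0] + 2.0 * A[0, 1] + A[1, 1])
    hi = 2.0 / (Dq[0, 0] + 2.0 * Dq[0, 1] + Dq[1, 1])
    return (lo, hi)


def _exact_offdiag_interval(A: np.ndarray, Dq: np.ndarray) -> Tuple[float, float]:
    """Exact PD region for S + delta*(e_i e_j' + e_j e_i') and the matching D step.

    Roots of the rank-2 determinant ratios (1 + d a_ij)^2 - d^2 a_ii a_jj and
    (1 - d d_ij)^2 - d^2 d_ii d_jj.
    """
    sa = np.sqrt(max(A[0, 0] * A[1, 1], 0.0))
    sd = np.sqrt(max(Dq[0, 0] * Dq[1, 1], 0.0))
    lo_S = -1.0 / (sa + A[0, 1]) if sa + A[0, 1] > 0 else -np.inf
    hi_S = 1.0 / (sa - A[0, 1]) if sa - A[0, 1] > 0 else np.inf
    lo_D = 1.0 / (Dq[0, 1] - sd) if Dq[0, 1] - sd < 0 else -np.inf
    hi_D = 1.0 / (Dq[0, 1] + sd) if Dq[0, 1] + sd > 0 else np.inf
    return (max(lo_S, lo_D), min(hi_S, hi_D))


def _shrink(lo, hi, eps):
    lo, hi = lo + eps, hi - eps
    if lo >= hi:
        return (0.0, 0.0)
    return (min(lo, 0.0), max(hi, 0.0))


# ---------------------------------------------------------------------------
# Coordinate updates
# ---------------------------------------------------------------------------

def me_coordinate_update(state: SolverState, i: int, j: int, m: int,
                         eps: float = 1e-6) -> float:
    """Entropy-maximizing step for entry (i, j) of S.

    Diagonal entries have the closed form delta = (m s - d)/((m+1) s d) with
    s = (S^-1)_ii, d = (D^-1)_ii, which is always interior.  Off-diagonal
    entries maximize the rank-2 determinant-ratio objective
    g(delta) = log((1 - delta d_ij)^2 - delta^2 d_ii d_jj)
             + m log((1 + delta a_ij)^2 - delta^2 a_ii a_jj)
    numerically over the exact feasible interval; g(0) = 0 so the step never
    degrades the objective.
    """
    if i == j:
        a = state.quads_S([i])[0, 0]
        d = state.quads_D([i])[0, 0]
        delta = (m * a - d) / ((m + 1) * a * d)
        lo, hi = _shrink(-1.0 / a, 1.0 / d, eps)
        return float(np.clip(delta, lo, hi))
    A = state.quads_S([i, j])
    Dq = state.quads_D([i, j])
    lo, hi = _shrink(*_exact_offdiag_interval(A, Dq), eps)
    if lo == hi:
        return 0.0

    def neg_g(delta):
        tS = (1.0 + delta * A[0, 1]) ** 2 - delta**2 * A[0, 0] * A[1, 1]
        tD = (1.0 - delta * Dq[0, 1]) ** 2 - delta**2 * Dq[0, 0] * Dq[1, 1]
        if tS <= 0.0 or tD <= 0.0:
            return np.inf
        return -(np.log(tD) + m * np.log(tS))

    res = minimize_scalar(neg_g, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    delta = float(res.x)
    if neg_g(delta) > 0.0:  # never accept a step worse than staying put
        return 0.0
    return delta


def _mvr_line_deltas(state: SolverState, i: int, j: int, m: int):
    """Return f(delta) = change in Tr(G_S^-1) along the coordinate line."""
    if i == j:
        A, A2 = state._inv_cols(state.C, [i])
        Dd, D2 = state._inv_cols(state.L, [i])
        a, w = A[0, 0], A2[0, 0]
        d, wd = Dd[0, 0], D2[0, 0]

        def f(delta):
            den_s = 1.0 + delta * a
            den_d = 1.0 - delta * d
            if den_s <= 0.0 or den_d <= 0.0:
                return np.inf
            return m * (-delta * w / den_s) + (1.0 / m) * (delta * wd / den_d)

        return f
    A, A2 = state._inv_cols(state.C, [i, j])
    Dd, D2 = state._inv_cols(state.L, [i, j])
    X = np.array([[0.0, 1.0], [1.0, 0.0]])

    def f(delta):
        if delta == 0.0:
            return 0.0
        Winv = X / delta
        try:
            M_s = np.linalg.inv(Winv + A)
            M_d = np.linalg.inv(Dd - Winv)
        except np.linalg.LinAlgError:
            return np.inf
        dS = -np.trace(M_s @ A2)
        dD = -np.trace(M_d @ D2)
        val = m * dS + (1.0 / m) * dD
        # reject deltas outside the PD region (detected via det ratios)
        tS = (1.0 + delta * A[0, 1]) ** 2 - delta**2 * A[0, 0] * A[1, 1]
        tD = (1.0 - delta * Dd[0, 1]) ** 2 - delta**2 * Dd[0, 0] * Dd[1, 1]
        if tS <= 0.0 or tD <= 0.0:
            return np.inf
        return val

    return f


def generic_coordinate_update(state: SolverState, i: int, j: int, m: int,
                              method: str, eps: float = 1e-6) -> float:
    """1-D minimization of the mvr or sdp objective along coordinate (i, j).

    ``sdp``: the line restriction is piecewise linear in the single entry, so
    the minimizer is Sigma_ij - S_ij clipped to the feasible interval.
    ``mvr``: bounded scalar minimization of the exact low-rank trace-update
    formula.  Both return a step no worse than 0.
    """
    if i == j:
        a = state.quads_S([i])[0, 0]
        d = state.quads_D([i])[0, 0]
        lo, hi = _shrink(-1.0 / a, 1.0 / d, eps)
    else:
        A = state.quads_S([i, j])
        Dq = state.quads_D([i, j])
        lo, hi = _shrink(*_exact_offdiag_interval(A, Dq), eps)
    if lo == hi:
        return 0.0
    if method == "sdp":
        return float(np.clip(state.sigma[i, j] - state.S[i, j], lo, hi))
    if method != "mvr":
        raise ValidationError("generic_coordinate_update handles methods 'mvr' and 'sdp'")
    f = _mvr_line_deltas(state, i, j, m)
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    delta = float(res.x)
    if f(delta) > 0.0:
        return 0.0
    return delta


# ---------------------------------------------------------------------------
# PCA updates
# ---------------------------------------------------------------------------

def pca_update(state: SolverState, v: np.ndarray, m: int, method: str,
               eps: float = 1e-6) -> float:
    """Step size along the rank-1 direction v v' (v an eigenvector of
    the block-diagonal part of Sigma, so the outer product respects the block
    pattern).

    For maxent the closed form delta = (m a_s - a_d)/((m+1) a_s a_d) with
    a_s = v'S^-1 v, a_d = v'D^-1 v is always interior to the exact region
    (-1/a_s, 1/a_d).  For mvr/sdp the step is found by bounded 1-D
    minimization over that region.
    """
    blocks = np.unique(state.group_of[np.abs(v) > 1e-14])
    if blocks.size > 1:
        raise ValidationError("PCA direction does not respect the block pattern")
    a_s, w_s = state.quad_vec(state.C, v)
    a_d, w_d = state.quad_vec(state.L, v)
    lo, hi = _shrink(-1.0 / a_s, 1.0 / a_d, eps)
    if lo == hi:
        return 0.0
    if method == "maxent":
        delta = (m * a_s - a_d) / ((m + 1) * a_s * a_d)
        return float(np.clip(delta, lo, hi))
    if method == "mvr":

        def f(delta):
            den_s = 1.0 + delta * a_s
            den_d = 1.0 - delta * a_d
            if den_s <= 0.0 or den_d <= 0.0:
                return np.inf
            return m * (-delta * w_s / den_s) + (1.0 / m) * (delta * w_d / den_d)

        res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        delta = float(res.x)
        return delta if f(delta) <= 0.0 else 0.0
    if method == "sdp":
        g = state.partition.groups[blocks[0] - 1]
        blk = np.ix_(g, g)
        Sb = state.S[blk]
        Tb = state.sigma[blk]
        vb = v[g]
        outer = np.outer(vb, vb)
        nz = np.abs(outer) > 1e-14
        bps = (Tb - Sb)[nz] / outer[nz]
        cands = np.concatenate([[lo, 0.0, hi], bps[(bps > lo) & (bps < hi)]])
        vals = [np.abs(Sb + t * outer - Tb).sum() for t in cands]
        delta = float(cands[int(np.argmin(vals))])
        base = np.abs(Sb - Tb).sum()
        return delta if min(vals) <= base else 0.0
    raise ValidationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Applying updates
# ---------------------------------------------------------------------------

def apply_update(state: SolverState, delta: float, i: int = None, j: int = None,
                 v: np.ndarray = None) -> None:
    """Apply S <- S + delta*U (coordinate) or S <- S + delta*v v' (PCA),
    updating S, D and both Cholesky factors via rank-1 update/downdate.

    A failed downdate (numerical loss of positive definiteness at the
    boundary) triggers a full refactorization with a warning.
    """
    if delta == 0.0:
        return
    if v is not None:
        state.S += delta * np.outer(v, v)
        state.D -= delta * np.outer(v, v)
        x = np.sqrt(abs(delta)) * v
        ok_c = chol_update(state.C, x, downdate=delta < 0)
        ok_l = chol_update(state.L, x, downdate=delta > 0)
    elif i == j:
        state.S[i, i] += delta
        state.D[i, i] -= delta
        x = np.zeros(state.p)
        x[i] = np.sqrt(abs(delta))
        ok_c = chol_update(state.C, x, downdate=delta < 0)
        ok_l = chol_update(state.L, x, downdate=delta > 0)
    else:
        state.S[i, j] += delta
        state.S[j, i] += delta
        state.D[i, j] -= delta
        state.D[j, i] -= delta
        # delta*(e_i e_j' + e_j e_i') = delta*(x x' - y y') with
        # x = (e_i + e_j)/sqrt(2), y = (e_i - e_j)/sqrt(2)
        r = np.sqrt(abs(delta) / 2.0)
        x = np.zeros(state.p)
        y = np.zeros(state.p)
        x[i], x[j] = r, r
        y[i], y[j] = r, -r
        up, down = (x, y) if delta > 0 else (y, x)
        ok_c = chol_update(state.C, up, downdate=False)
        ok_c = chol_update(state.C, down, downdate=True) and ok_c
        ok_l = chol_update(state.L, down, downdate=False)
        ok_l = chol_update(state.L, up, downdate=True) and ok_l
    if not (ok_c and ok_l):
        warnings.warn("Cholesky downdate lost positive definiteness; refactorizing")
        state.rebuild()


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def _block_whitener(sigma: np.ndarray, partition: GroupPartition) -> np.ndarray:
    """Block-diagonal matrix with blocks Sigma_g^{-1/2}."""
    p = sigma.shape[0]
    B = np.zeros((p, p))
    for g in partition.groups:
        blk = sigma[np.ix_(g, g)]
        w, V = np.linalg.eigh(blk)
        if w[0] <= 0:
            raise ValidationError("non-positive-definite group block; regularize Sigma first")
        B[np.ix_(g, g)] = (V / np.sqrt(w)) @ V.T
    return B


def _sigma_block(sigma: np.ndarray, partition: GroupPartition) -> np.ndarray:
    out = np.zeros_like(sigma)
    for g in partition.groups:
        out[np.ix_(g, g)] = sigma[np.ix_(g, g)]
    return out


def _equi_tau(sigma, partition, m):
    B = _block_whitener(sigma, partition)
    lam = float(np.linalg.eigvalsh(B @ sigma @ B)[0])
    return min(1.0, ((m + 1) / m) * lam), B


def solve_equi(model: CorrelationModel, partition: GroupPartition, m: int = 1,
               eps_boundary: float = 1e-6) -> KnockoffSolution:
    """Closed-form equivariant solution S_g = tau Sigma_g.

    tau = min{1, ((m+1)/m) lambda_min(B Sigma B)} with B the block whitener
    diag(Sigma_g^{-1/2}); the returned S is shrunk by (1 - eps_boundary) to
    stay strictly inside the feasible cone.  ``gamma_equi`` records tau
    before the shrink.
    """
    sigma = model.sigma
    tau, B = _equi_tau(sigma, partition, m)
    S = tau * (1.0 - eps_boundary) * _sigma_block(sigma, partition)
    return KnockoffSolution(
        S=S, m=m, method="equi", partition=partition, sigma=sigma,
        objective_trace=[_sdp_loss(S, sigma, partition)],
        gamma_equi=tau, B_whiten=B, eps_boundary=eps_boundary,
    )


def _pca_directions(sigma: np.ndarray, partition: GroupPartition) -> np.ndarray:
    """Eigenvectors of diag(Sigma_1, ..., Sigma_g), embedded in R^p."""
    p = sigma.shape[0]
    dirs = np.zeros((p, p))
    col = 0
    for g in partition.groups:
        w, V = np.linalg.eigh(sigma[np.ix_(g, g)])
        for k in range(g.size):
            dirs[g, col] = V[:, k]
            col += 1
    return dirs


def _state_objective(state: SolverState, method: str) -> float:
    if method == "sdp":
        return _sdp_loss(state.S, state.sigma, state.partition)
    if method == "maxent":
        return -2.0 * (state.m * np.log(np.diag(state.C)).sum()
                       + np.log(np.diag(state.L)).sum())
    Cinv = solve_triangular(state.C, np.eye(state.p), lower=True)
    Linv = solve_triangular(state.L, np.eye(state.p), lower=True)
    return state.m * float((Cinv**2).sum()) + (1.0 / state.m) * float((Linv**2).sum())


def solve_group_knockoff(
    model: CorrelationModel,
    partition: GroupPartition,
    options: Optional[SolverOptions] = None,
) -> KnockoffSolution:
    """Optimize the block-diagonal S for the selected objective.

    Starts from the strictly feasible interior point S0 = (tau_equi/2)
    Sigma_block and alternates full coordinate-descent sweeps (diagonal
    entries first, then the upper triangle of each block in row-major order)
    with full PCA sweeps over the eigenvectors of Sigma_block, until the
    relative objective change per round drops below ``tol_obj`` or
    ``max_sweeps`` rounds are reached.  Every step is clamped to the exact
    feasible region and accepted only if it does not increase the objective,
    so the per-round objective trace is non-increasing.
    """
    options = options or SolverOptions()
    if options.method == "equi":
        return solve_equi(model, partition, options.m, options.eps_boundary)
    sigma = model.sigma
    m = options.m
    eps = options.eps_boundary
    tau, _ = _equi_tau(sigma, partition, m)
    S0 = 0.5 * tau * _sigma_block(sigma, partition)
    state = SolverState(sigma, partition, S0, m)
    dirs = _pca_directions(sigma, partition)

    trace = [_state_objective(state, options.method)]
    for _ in range(options.max_sweeps):
        for phase in options.alternation:
            if phase == "coord":
                for g in partition.groups:
                    mem = np.sort(g)
                    for i in mem:
                        if options.method == "maxent":
                            d = me_coordinate_update(state, i, i, m, eps)
                        else:
                            d = generic_coordinate_update(state, i, i, m, options.method, eps)
                        apply_update(state, d, i=i, j=i)
                    for a in range(mem.size):
                        for b in range(a + 1, mem.size):
                            i, j = mem[a], mem[b]
                            if options.method == "maxent":
                                d = me_coordinate_update(state, i, j, m, eps)
                            else:
                                d = generic_coordinate_update(state, i, j, m, options.method, eps)
                            apply_update(state, d, i=i, j=j)
            else:
                for k in range(state.p):
                    v = dirs[:, k]
                    d = pca_update(state, v, m, options.method, eps)
                    apply_update(state, d, v=v)
        obj = _state_objective(state, options.method)
        trace.append(obj)
        prev, cur = trace[-2], trace[-1]
        if abs(prev - cur) <= options.tol_obj * max(abs(prev), 1e-10):
            break

    S = 0.5 * (state.S + state.S.T)
    return KnockoffSolution(
        S=S, m=m, method=options.method, partition=partition, sigma=sigma,
        objective_trace=trace, eps_boundary=eps,
    )
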