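"""Group definition, key-variable selection, and within-group conditional laws.

Variants in high linkage disequilibrium cannot be disentangled by conditional
testing, so inference is moved to groups of correlated variables.  Groups are
defined by average-linkage hierarchical clustering of the correlation matrix
with dissimilarity ``1 - |r|`` and a strict cut at height ``1 - cutoff``
(cutoff 0.5 means variables merging at |r| > 0.5 share a group).

Within each group a small set of *key* variables can be chosen so that,
approximately, the remaining (non-key) members are independent of everything
outside the group given the keys.  Knockoffs then only need to be optimized
and sampled for the keys; non-key knockoffs are regenerated from the
within-group conditional regression.  ``select_key_variables`` performs a
greedy forward search until the keys explain a fraction ``c`` of the
within-group variation; ``conditional_regressions`` computes the Gaussian
conditional law of the non-keys given the keys; ``ci_implied_sigma`` builds
the covariance of the Gaussian that satisfies the group-key conditional
independence property exactly (used to validate the construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .covmodels import CorrelationModel, ValidationError

__all__ = [
    "GroupPartition",
    "KeySelection",
    "ConditionalRegression",
    "hierarchical_cluster_groups",
    "partition_from_labels",
    "select_key_variables",
    "conditional_regressions",
    "ci_implied_sigma",
]

_STRICT_CUT = 1e-10


@dataclass(frozen=True)
class GroupPartition:
    """A partition of {0..p-1} into groups, with a contiguity permutation.

    ``assignment`` holds 1-based group labels in the original variable order.
    ``groups`` lists the member indices (original order) of each group;
    ``perm`` is a permutation of the variables under which group members are
    contiguous (``assignment[perm]`` is sorted).
    """

    assignment: np.ndarray
    groups: List[np.ndarray]
    perm: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        object.__setattr__(self, "perm", np.asarray(self.perm, dtype=int))
        object.__setattr__(self, "groups", [np.asarray(g, dtype=int) for g in self.groups])
        p = a.size
        seen = np.concatenate(self.groups) if self.groups else np.array([], dtype=int)
        if sorted(seen.tolist()) != list(range(p)):
            raise ValidationError("groups do not partition the variable indices")
        if any(g.size == 0 for g in self.groups):
            raise ValidationError("empty group")
        if not np.all(np.diff(a[self.perm]) >= 0):
            raise ValidationError("stored permutation does not make groups contiguous")

    @property
    def p(self) -> int:
        return self.assignment.size

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def sizes(self) -> np.ndarray:
        return np.array([g.size for g in self.groups])

    def to_frame(self, variant_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"group": self.assignment})
        if variant_meta is not None:
            df = pd.concat([variant_meta.reset_index(drop=True), df], axis=1)
        return df


@dataclass(frozen=True)
class KeySelection:
    """Per-group key (star) / non-key (dagger) index split at target fraction c."""

    partition: GroupPartition
    star: List[np.ndarray]
    dagger: List[np.ndarray]
    c: float

    def __post_init__(self):
        object.__setattr__(self, "star", [np.asarray(s, dtype=int) for s in self.star])
        object.__setattr__(self, "dagger", [np.asarray(d, dtype=int) for d in self.dagger])
        for g, s, d in zip(self.partition.groups, self.star, self.dagger):
            if s.size == 0:
                raise ValidationError("every group needs at least one key variable")
            union = np.sort(np.concatenate([s, d]))
            if not np.array_equal(union, np.sort(g)):
                raise ValidationError("star/dagger do not partition the group")

    @property
    def key_indices(self) -> np.ndarray:
        """All key indices, sorted in original variable order."""
        return np.sort(np.concatenate(self.star))

    @property
    def n_keys(self) -> int:
        return sum(s.size for s in self.star)


@dataclass(frozen=True)
class ConditionalRegression:
    """Gaussian conditional law of non-key members given their group's keys.

    For group gamma with key block ``Sigma_**`` and non-key rows ``Sigma_d*``:
    ``B = Sigma_d* Sigma_**^{-1}`` and ``R = Sigma_dd - B Sigma_*d`` (PSD).
    """

    keys: KeySelection
    B: List[np.ndarray]
    R: List[np.ndarray]


def hierarchical_cluster_groups(model: CorrelationModel, cutoff: float = 0.5) -> GroupPartition:
    """Average-linkage clustering of variables at dissimilarity ``1 - |r|``.

    The dendrogram is cut strictly below height ``1 - cutoff``: pairs with
    |correlation| exactly equal to ``cutoff`` do not merge.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValidationError("cutoff must lie in (0, 1)")
    p = model.p
    if p == 1:
        return partition_from_labels(np.array([1]))
    d = 1.0 - np.abs(model.sigma)
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(Z, t=(1.0 - cutoff) - _STRICT_CUT, criterion="distance")
    return partition_from_labels(labels)


def partition_from_labels(labels: Sequence[int]) -> GroupPartition:
    """Build a :class:`GroupPartition` from raw cluster labels.

    Groups are numbered 1..g by order of first appearance, and the contiguity
    permutation is the stable sort by that numbering, so the result is
    invariant (up to relabeling) under simultaneous permutation of the input.
    """
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    order = {labels[i]: rank + 1 for rank, i in enumerate(sorted(first))}
    assignment = np.array([order[l] for l in labels], dtype=int)
    perm = np.argsort(assignment, kind="stable")
    groups = [np.flatnonzero(assignment == g) for g in range(1, assignment.max() + 1)]
    return GroupPartition(assignment=assignment, groups=groups, perm=perm)


def _explained_variance(sigma: np.ndarray, members: np.ndarray, keys: np.ndarray) -> float:
    """Sum over group members of R^2 given the key set (unit variances)."""
    Skk = sigma[np.ix_(keys, keys)]
    Smk = sigma[np.ix_(members, keys)]
    sol = np.linalg.solve(Skk, Smk.T)
    return float(np.sum(Smk * sol.T))


def select_key_variables(
    model: CorrelationModel, partition: GroupPartition, c: float
) -> KeySelection:
    """Greedy forward selection of key variables per group.

    Starting from the variable with the largest explained variance, variables
    are added one at a time (largest EV gain, ties to the lowest index) until
    the keys explain at least a fraction ``c`` of the within-group variation,
    EV(K)/|A_gamma| >= c.  With ``c = 1`` every variable is a key and the
    conditional-independence construction reduces to plain group knockoffs.
    """
    if not (0.0 < c <= 1.0):
        raise ValidationError("c must lie in (0, 1]")
    star, dagger = [], []
    for members in partition.groups:
        k = members.size
        if c >= 1.0 or k == 1:
            star.append(members.copy())
            dagger.append(np.array([], dtype=int))
            continue
        chosen: list[int] = []
        remaining = list(members)
        ev = 0.0
        while remaining and ev / k < c - 1e-12:
            best_gain, best_j = -np.inf, None
            for j in remaining:
                cand = np.array(chosen + [j])
                try:
                    gain = _explained_variance(model.sigma, members, cand) - ev
                except np.linalg.LinAlgError:
                    continue
                if gain > best_gain + 1e-12:
                    best_gain, best_j = gain, j
            if best_j is None:  # all candidates singular: stop
                break
            chosen.append(best_j)
            ev += best_gain
        star.append(np.array(sorted(chosen), dtype=int))
        dagger.append(np.array(sorted(set(members) - set(chosen)), dtype=int))
    return KeySelection(partition=partition, star=star, dagger=dagger, c=float(c))


def conditional_regressions(model: CorrelationModel, keys: KeySelection) -> ConditionalRegression:
    """Compute B and R of the non-key | key conditional law for every group.

    Only within-group blocks of Sigma are used: under group-key conditional
    independence the law of the non-keys given *all* keys depends only on the
    keys of their own group.
    """
    Bs, Rs = [], []
    sigma = model.sigma
    for s, d in zip(keys.star, keys.dagger):
        if d.size == 0:
            Bs.append(np.zeros((0, s.size)))
            Rs.append(np.zeros((0, 0)))
            continue
        Sss = sigma[np.ix_(s, s)]
        Sds = sigma[np.ix_(d, s)]
        Sdd = sigma[np.ix_(d, d)]
        try:
            B = np.linalg.solve(Sss, Sds.T).T
        except np.linalg.LinAlgError as e:
            raise ValidationError(f"singular key submatrix: {e}") from e
        R = Sdd - B @ Sds.T
        R = 0.5 * (R + R.T)
        Bs.append(B)
        Rs.append(R)
    return ConditionalRegression(keys=keys, B=Bs, R=Rs)


def ci_implied_sigma(model: CorrelationModel, keys: KeySelection) -> CorrelationModel:
    """Covariance of the Gaussian satisfying group-key conditional independence.

    Within-group blocks are preserved.  Cross-group entries are routed through
    the key variables: a non-key row j in group gamma contributes
    ``B_gamma[j, :] @ Sigma[star_gamma, k]`` and, when the other side is also
    non-key, the projection is applied on both sides.  Idempotent, symmetric,
    and unit-diagonal by construction.
    """
    reg = conditional_regressions(model, keys)
    sigma = model.sigma
    p = model.p
    # M maps the key coordinates to all p coordinates under the CI structure:
    # rows of keys pick themselves, non-key rows apply B within their group.
    key_idx = keys.key_indices
    pos = {j: t for t, j in enumerate(key_idx)}
    M = np.zeros((p, key_idx.size))
    for s, d, B in zip(keys.star, keys.dagger, reg.B):
        cols = [pos[j] for j in s]
        for j in s:
            M[j, pos[j]] = 1.0
        if d.size:
            M[np.ix_(d, cols)] = B
    out = M @ sigma[np.ix_(key_idx, key_idx)] @ M.T
    # restore exact within-group blocks (the projection only governs cross-group entries)
    for g in keys.partition.groups:
        out[np.ix_(g, g)] = sigma[np.ix_(g, g)]
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return CorrelationModel(sigma=out, variant_meta=model.variant_meta, gamma_reg=model.gamma_reg)
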