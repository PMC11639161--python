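"""End-to-end power/FDR simulation harness.

Each replicate draws a Gaussian design from one of the synthetic covariance
families, simulates a sparse linear response, defines groups from the
*sample* correlation of the observed design (as a practitioner would),
solves for S on the generator covariance, samples m knockoff copies, scores
groups with the Lasso importance statistic, and applies the
multiple-knockoff filter.  Power is the fraction of causal groups
discovered (a group is causal if it contains at least one causal feature);
FDR is the fraction of discovered groups containing none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .covmodels import CorrelationModel, CovarianceSpec, make_covariance, regularize
from .grouping import (
    GroupPartition,
    hierarchical_cluster_groups,
    partition_from_labels,
    select_key_variables,
    conditional_regressions,
)
from .solver import SolverOptions, solve_group_knockoff
from .sampling import sample_knockoffs_gaussian, sample_knockoffs_group_key
from .filters import group_importance_lasso, run_filter
from .covmodels import ValidationError

__all__ = [
    "ExperimentConfig",
    "SimulationResult",
    "simulate_design",
    "simulate_response",
    "evaluate_power_fdr",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Study conditions for one power/FDR experiment."""

    cov_spec: CovarianceSpec
    n: int = 750
    k: int = 10
    effect_sd: float = 1.0
    m: int = 5
    method: str = "maxent"
    q: float = 0.1
    cutoff: float = 0.5
    c: float = 1.0  # key-variable fraction; 1 disables the CI construction
    reps: int = 10
    seed: int = 0
    groups_from_sample_corr: bool = True
    solve_on_true_sigma: bool = True
    lasso_cv: int = 10
    max_sweeps: int = 100
    tol_obj: float = 1e-4

    def __post_init__(self):
        if self.k > self.cov_spec.p:
            raise ValidationError("k cannot exceed p")
        if not (0.0 < self.q < 1.0):
            raise ValidationError("q must lie in (0, 1)")
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")


@dataclass
class SimulationResult:
    power: List[float] = field(default_factory=list)
    fdr: List[float] = field(default_factory=list)
    n_selected: List[int] = field(default_factory=list)
    failed_reps: List[int] = field(default_factory=list)

    @property
    def power_mean(self) -> float:
        return float(np.mean(self.power)) if self.power else 0.0

    @property
    def fdr_mean(self) -> float:
        return float(np.mean(self.fdr)) if self.fdr else 0.0

    @property
    def power_se(self) -> float:
        return float(np.std(self.power, ddof=1) / np.sqrt(len(self.power))) if len(self.power) > 1 else 0.0

    @property
    def fdr_se(self) -> float:
        return float(np.std(self.fdr, ddof=1) / np.sqrt(len(self.fdr))) if len(self.fdr) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "power_mean": self.power_mean,
            "power_se": self.power_se,
            "fdr_mean": self.fdr_mean,
            "fdr_se": self.fdr_se,
            "reps": len(self.power),
        }


def simulate_design(sigma: np.ndarray, n: int, seed: Optional[int]) -> np.ndarray:
    """n i.i.d. rows from N(0, Sigma), then column-standardized."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma + 1e-12 * np.eye(sigma.shape[0]))
    X = rng.standard_normal((n, sigma.shape[0])) @ L.T
    X -= X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return X / sd


def simulate_response(
    X: np.ndarray, k: int, effect_sd: float, seed: Optional[int]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse linear response y = X beta + N(0, 1) noise.

    k causal indices are drawn uniformly without replacement; their effects
    are N(0, effect_sd^2).
    """
    n, p = X.shape
    if k > p:
        raise ValidationError("k cannot exceed p")
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(p, size=k, replace=False))
    beta = np.zeros(p)
    beta[causal] = rng.normal(0.0, effect_sd, size=k)
    y = X @ beta + rng.standard_normal(n)
    return y, beta, causal


def evaluate_power_fdr(
    selected: Sequence[int], partition: GroupPartition, causal_idx: Sequence[int]
) -> Tuple[float, float]:
    """Group-level power and false discovery proportion.

    ``selected`` holds 1-based group labels.  A group is causal when it
    contains at least one causal feature index.  Empty denominators are
    defined as 0.
    """
    causal_idx = np.asarray(causal_idx, dtype=int)
    causal_groups = {
        g + 1 for g, members in enumerate(partition.groups)
        if np.intersect1d(members, causal_idx).size > 0
    }
    sel = set(int(s) for s in selected)
    power = len(sel & causal_groups) / len(causal_groups) if causal_groups else 0.0
    fdp = len(sel - causal_groups) / max(1, len(sel))
    return power, fdp


def _one_rep(config: ExperimentConfig, rep_seed: int) -> Tuple[float, float, int]:
    spec = config.cov_spec
    model = regularize(make_covariance(
        CovarianceSpec(kind=spec.kind, p=spec.p, seed=rep_seed, params=spec.params)
    ))
    X = simulate_design(model.sigma, config.n, rep_seed + 1)
    y, _, causal = simulate_response(X, config.k, config.effect_sd, rep_seed + 2)

    if config.groups_from_sample_corr:
        corr = np.corrcoef(X, rowvar=False)
        corr = 0.5 * (corr + corr.T)
        np.fill_diagonal(corr, 1.0)
        partition = hierarchical_cluster_groups(CorrelationModel(sigma=corr), config.cutoff)
    else:
        partition = hierarchical_cluster_groups(model, config.cutoff)

    sigma_solver = model if config.solve_on_true_sigma else regularize(
        CorrelationModel(sigma=np.corrcoef(X, rowvar=False))
    )
    options = SolverOptions(
        method=config.method, m=config.m,
        max_sweeps=config.max_sweeps, tol_obj=config.tol_obj,
    )
    if config.c < 1.0:
        keys = select_key_variables(sigma_solver, partition, config.c)
        regs = conditional_regressions(sigma_solver, keys)
        key_idx = keys.key_indices
        sub_sigma = sigma_solver.sigma[np.ix_(key_idx, key_idx)]
        sub_model = regularize(CorrelationModel(sigma=sub_sigma))
        sub_labels = partition.assignment[key_idx]
        sub_part = partition_from_labels(sub_labels)
        sol = solve_group_knockoff(sub_model, sub_part, options)
        sample = sample_knockoffs_group_key(X, sigma_solver, keys, regs, sol, config.m, rep_seed + 3)
    else:
        sol = solve_group_knockoff(sigma_solver, partition, options)
        sample = sample_knockoffs_gaussian(X, sigma_solver.sigma, sol.S, config.m, rep_seed + 3)

    Z, Zt = group_importance_lasso(
        X, sample.values, y, partition, cv=config.lasso_cv, seed=rep_seed % (2**31),
    )
    result = run_filter(Z, Zt, config.q, config.m)
    power, fdp = evaluate_power_fdr(result.selected, partition, causal)
    return power, fdp, result.selected.size


def run_experiment(config: ExperimentConfig, progress: bool = False) -> SimulationResult:
    """Run all replicates; per-rep seeds spawn deterministically from the master seed."""
    result = SimulationResult()
    for rep in range(config.reps):
        rep_seed = int((config.seed * 1_000_003 + rep * 101) % (2**31 - 1))
        try:
            power, fdp, nsel = _one_rep(config, rep_seed)
        except np.linalg.LinAlgError:
            result.failed_reps.append(rep)
            continue
        result.power.append(power)
        result.fdr.append(fdp)
        result.n_selected.append(nsel)
        if progress:  # pragma: no cover
            print(f"rep {rep + 1}/{config.reps}: power={power:.3f} fdp={fdp:.3f}", flush=True)
    return result
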