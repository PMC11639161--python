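"""scikit-learn style estimators wrapping the group-knockoff machinery.

``GroupKnockoff`` is a transformer: ``fit`` learns the group partition and
the optimal S for the feature correlation matrix, ``transform`` draws m
knockoff copies for the rows it is given.  ``KnockoffFilter`` is a selector:
``fit(X, y)`` runs construction, Lasso importance, and the
multiple-knockoff filter, exposing the selection through ``support_`` and
``selected_groups_``.  Both compose with sklearn pipelines and
``clone``/``get_params``/``set_params``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .covmodels import CorrelationModel, ValidationError, regularize
from .grouping import hierarchical_cluster_groups, partition_from_labels
from .solver import SolverOptions, solve_group_knockoff
from .sampling import sample_knockoffs_gaussian
from .filters import group_importance_lasso, run_filter

__all__ = ["GroupKnockoff", "KnockoffFilter"]


class GroupKnockoff(BaseEstimator, TransformerMixin):
    """Second-order Gaussian group knockoff generator.

    Parameters
    ----------
    method : {'maxent', 'mvr', 'sdp', 'equi'}
        Objective for the S optimization.
    m : int
        Number of knockoff copies per feature.
    cutoff : float
        Correlation cutoff for the average-linkage group clustering.
    sigma : ndarray, optional
        Known feature correlation matrix; estimated from X when omitted.
    groups : array-like, optional
        Precomputed group labels (1-based); clustered from the correlation
        matrix when omitted.
    random_state : int, optional
        Seed for knockoff sampling in :meth:`transform`.

    Attributes
    ----------
    S_ : ndarray of shape (p, p)
        Optimized block-diagonal S.
    partition_ : GroupPartition
    solution_ : KnockoffSolution
    sigma_ : ndarray of shape (p, p)
        Correlation matrix actually used (after regularization).
    """

    def __init__(self, method: str = "maxent", m: int = 1, cutoff: float = 0.5,
                 sigma: Optional[np.ndarray] = None, groups=None,
                 max_sweeps: int = 100, tol_obj: float = 1e-4,
                 random_state: Optional[int] = None):
        self.method = method
        self.m = m
        self.cutoff = cutoff
        self.sigma = sigma
        self.groups = groups
        self.max_sweeps = max_sweeps
        self.tol_obj = tol_obj
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.sigma is not None:
            sigma = np.asarray(self.sigma, dtype=float)
        else:
            if X.shape[0] < 3:
                raise ValidationError("need >= 3 rows to estimate a correlation matrix")
            sigma = np.corrcoef(X, rowvar=False)
        sigma = 0.5 * (sigma + sigma.T)
        np.fill_diagonal(sigma, 1.0)
        model = regularize(CorrelationModel(sigma=sigma))
        if self.groups is not None:
            partition = partition_from_labels(np.asarray(self.groups))
        else:
            partition = hierarchical_cluster_groups(model, self.cutoff)
        options = SolverOptions(method=self.method, m=self.m,
                                max_sweeps=self.max_sweeps, tol_obj=self.tol_obj)
        self.solution_ = solve_group_knockoff(model, partition, options)
        self.S_ = self.solution_.S
        self.partition_ = partition
        self.sigma_ = model.sigma
        self.n_features_in_ = sigma.shape[0]
        return self

    def transform(self, X):
        """Draw m knockoff copies for each row of X (copy-major columns)."""
        check_is_fitted(self, "S_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("X has a different number of features than fit")
        sample = sample_knockoffs_gaussian(
            X, self.sigma_, self.S_, self.m, self.random_state
        )
        return sample.values


class KnockoffFilter(BaseEstimator):
    """FDR-controlled group selection with multiple simultaneous knockoffs.

    ``fit(X, y)`` constructs knockoffs, computes group Lasso importances,
    and applies the multiple-knockoff filter at level ``q``.

    Attributes
    ----------
    support_ : bool array of shape (p,)
        True for features belonging to a selected group.
    selected_groups_ : int array
        1-based labels of selected groups.
    w_ : ndarray of shape (g,)
        Per-group W statistics.
    threshold_ : float
    """

    def __init__(self, method: str = "maxent", m: int = 5, q: float = 0.1,
                 cutoff: float = 0.5, sigma: Optional[np.ndarray] = None,
                 groups=None, lasso_cv: int = 10,
                 random_state: Optional[int] = 0):
        self.method = method
        self.m = m
        self.q = q
        self.cutoff = cutoff
        self.sigma = sigma
        self.groups = groups
        self.lasso_cv = lasso_cv
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        gk = GroupKnockoff(method=self.method, m=self.m, cutoff=self.cutoff,
                           sigma=self.sigma, groups=self.groups,
                           random_state=self.random_state)
        Xt = gk.fit(X).transform(X)
        self.knockoff_ = gk
        Z, Zt = group_importance_lasso(
            X, Xt, y, gk.partition_, cv=self.lasso_cv, seed=self.random_state,
        )
        res = run_filter(Z, Zt, self.q, self.m)
        self.result_ = res
        self.w_ = res.W
        self.threshold_ = res.threshold
        self.selected_groups_ = res.selected
        self.support_ = np.isin(gk.partition_.assignment, res.selected)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_
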