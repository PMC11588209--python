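"""Grouping by clustering per-species regression coefficients.

A deliberately naive baseline: regress the function on all ``S`` species
abundances at once (with intercept), then cluster the ``S`` scalar
coefficients with K-Means.  Species whose marginal association with the
function is similar end up in the same group.  When the regression is
under-determined (fewer than ``S + 1`` samples) the minimum-norm solution
is used and the fit is flagged.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from ._rng import child_seed
from .partition import Grouping
from .regression import fit_group_regression, group_abundances

__all__ = ["KMeansGrouper", "kmeans_grouping"]


class KMeansGrouper(BaseEstimator):
    """Cluster species into ``n_groups`` by their regression coefficients.

    Fitted attributes
    -----------------
    coefficients_ : the per-species coefficients fed to the clustering.
    labels_ : per-species group labels (canonical order).
    grouping_ : the resulting :class:`Grouping`.
    model_ : linear regression of y on the group abundances.
    underdetermined_ : True when n_samples < S + 1 (minimum-norm fit).
    """

    def __init__(self, n_groups: int = 2, n_init: int = 10, random_state=None):
        self.n_groups = n_groups
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, S = X.shape
        if not 1 <= self.n_groups < S:
            raise ValueError(f"need 1 <= n_groups < {S}, got {self.n_groups}")
        design = np.hstack([np.ones((n, 1)), X])
        beta, _, rank, _ = linalg.lstsq(design, y, lapack_driver="gelsy")
        self.underdetermined_ = bool(rank < S + 1)
        self.coefficients_ = beta[1:]  # intercept excluded from clustering

        km = KMeans(
            n_clusters=self.n_groups,
            init="k-means++",
            n_init=self.n_init,
            random_state=child_seed(self.random_state, 30),
        ).fit(self.coefficients_[:, None])
        self.grouping_ = Grouping.from_labels(km.labels_)
        self.labels_ = self.grouping_.to_labels()
        T = group_abundances(X, self.grouping_)
        self.model_ = fit_group_regression(T, y, order="linear")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.model_.predict(group_abundances(X, self.grouping_))


def kmeans_grouping(dataset, k: int, **options) -> Grouping:
    """Cluster a dataset's species into ``k`` groups; returns the Grouping."""
    est = KMeansGrouper(n_groups=k, **options).fit(dataset.abundance, dataset.function)
    return est.grouping_
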