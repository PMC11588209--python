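"""Group-abundance regression models and the AIC objective.

All grouping algorithms share the same machinery: collapse the abundance
table onto candidate group abundances ``T_ag = sum_{mu in group g} A_a_mu``
and regress the function on them, either linearly

    Y = b + sum_i c_i T_i

or with full quadratic terms (squares and cross products)

    Y = b + sum_i c_i T_i + sum_{i<=j} d_ij T_i T_j.

Fits are ordinary least squares; rank-deficient designs fall back to the
minimum-norm solution and are flagged.  The subset-selection objective used
by the genetic search is ``AIC = 2 kappa + n log(RSS / n)`` with ``kappa``
the number of selected species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .partition import Grouping

__all__ = [
    "GroupRegressionModel",
    "group_abundances",
    "fit_group_regression",
    "aic_score",
]


def group_abundances(abundance: np.ndarray, grouping: Grouping) -> np.ndarray:
    """Per-sample total abundance of each group, shape ``(n_samples, k)``.

    Columns follow the grouping's canonical group order.
    """
    A = np.asarray(abundance, dtype=float)
    if A.ndim != 2 or A.shape[1] != grouping.n_species:
        raise ValueError(
            f"abundance table has {A.shape[-1]} species but the grouping "
            f"covers {grouping.n_species}"
        )
    T = np.empty((A.shape[0], grouping.k))
    for g, idx in enumerate(grouping.member_arrays()):
        T[:, g] = A[:, idx].sum(axis=1)
    return T


def _quadratic_columns(T: np.ndarray) -> np.ndarray:
    """Columns ``T_i T_j`` for ``i <= j``, in row-major (i, j) order."""
    k = T.shape[1]
    iu, ju = np.triu_indices(k)
    return T[:, iu] * T[:, ju]


@dataclass(frozen=True)
class GroupRegressionModel:
    """A fitted intercept/linear(/quadratic) model over group abundances.

    ``quadratic`` is an upper-triangular ``(k, k)`` matrix holding ``d_ij``
    at ``[i, j]`` for ``i <= j`` (``None`` for linear models).  ``flagged``
    marks rank-deficient designs (minimum-norm fit) and zero-variance
    responses.
    """

    order: str  # "linear" | "quadratic"
    intercept: float
    linear: np.ndarray  # (k,)
    quadratic: np.ndarray | None  # (k, k) upper triangular, or None
    rss: float
    rmse: float
    n_samples: int
    rank: int
    flagged: bool = False

    @property
    def k(self) -> int:
        return len(self.linear)

    @property
    def n_coefficients(self) -> int:
        k = self.k
        return 1 + k + (k * (k + 1)) // 2 * (self.order == "quadratic")

    def predict(self, T: np.ndarray) -> np.ndarray:
        """Predicted function values for group-abundance rows ``T``."""
        T = np.asarray(T, dtype=float)
        if T.shape[-1] != self.k:
            raise ValueError(f"expected {self.k} group columns, got {T.shape[-1]}")
        T2 = np.atleast_2d(T)
        y = self.intercept + T2 @ self.linear
        if self.order == "quadratic":
            y = y + _quadratic_columns(T2) @ self.quadratic[np.triu_indices(self.k)]
        return y[0] if T.ndim == 1 else y


def fit_group_regression(
    T: np.ndarray, y: np.ndarray, order: str = "linear"
) -> GroupRegressionModel:
    """Least-squares fit of the function on group abundances.

    Uses QR with column pivoting; when the design is rank-deficient (e.g.
    duplicated group columns, or more coefficients than samples) the
    minimum-norm solution is returned and the model flagged.
    """
    if order not in ("linear", "quadratic"):
        raise ValueError(f"order must be 'linear' or 'quadratic', got {order!r}")
    T = np.atleast_2d(np.asarray(T, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = T.shape
    if y.shape != (n,):
        raise ValueError("response length must match the number of samples")

    cols = [np.ones((n, 1)), T]
    if order == "quadratic":
        cols.append(_quadratic_columns(T))
    X = np.hstack(cols)

    flagged = False
    if np.ptp(y) == 0:
        beta = np.zeros(X.shape[1])
        beta[0] = y[0] if n else 0.0
        rank = 1
        flagged = True
    else:
        beta, _, rank, _ = linalg.lstsq(X, y, lapack_driver="gelsy")
        if rank < X.shape[1]:
            flagged = True
    resid = y - X @ beta
    rss = float(resid @ resid)
    rmse = float(np.sqrt(rss / n))

    quad = None
    if order == "quadratic":
        quad = np.zeros((k, k))
        quad[np.triu_indices(k)] = beta[1 + k :]
    return GroupRegressionModel(
        order=order,
        intercept=float(beta[0]),
        linear=beta[1 : 1 + k].copy(),
        quadratic=quad,
        rss=rss,
        rmse=rmse,
        n_samples=n,
        rank=int(rank),
        flagged=flagged,
    )


def aic_score(kappa: int, n: int, rss: float) -> float:
    """``AIC = 2 kappa + n log(RSS / n)`` (natural log).

    ``kappa`` is the selected-subset size acting as the complexity penalty.
    A perfect fit (``RSS = 0``) maps to ``-inf`` and is always preferred.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        return -np.inf
    return 2.0 * kappa + n * np.log(rss / n)
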