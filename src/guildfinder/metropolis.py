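"""Metropolis search over the space of species partitions.

The algorithm maintains one candidate grouping per group count
``k = 1..k_max`` together with the RMSE of the regression of the function
on that grouping's group abundances (the "energy" ``E_k``).  Each step
picks a stored grouping uniformly at random and proposes a neighbour with
``k' = k +- 1`` by randomly splitting one group (probability ``p``) or
merging two (probability ``1 - p``); at the boundaries ``k = 1`` /
``k = k_max`` the only possible move is taken with probability 1.  The
proposal is evaluated and replaces the stored ``k'`` candidate with
probability ``min(1, exp(-beta (E' - E_k')))``; at the default
``beta = inf`` this accepts exactly when ``E' <= E_k'``, so every stored
energy is non-increasing over the run.  Storing candidates for all ``k``
keeps a large move set available, which is why the zero-temperature limit
does not get stuck in practice.

The regression may be linear or fully quadratic in the group abundances;
the quadratic variant has ``1 + k + k(k+1)/2`` coefficients, quadratic in
``k`` rather than in the number of species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._rng import child_rng
from .partition import Grouping, random_grouping
from .regression import GroupRegressionModel, fit_group_regression, group_abundances

__all__ = ["MetropolisState", "MetropolisGrouper", "metropolis_fit", "propose_move"]


@dataclass
class MetropolisState:
    """The stored candidate list, energies, models and acceptance trace."""

    groupings: list[Grouping]  # index k-1 holds the k-group candidate
    energies: np.ndarray  # (k_max,) RMSE of each stored candidate
    models: list[GroupRegressionModel]
    k_max: int
    beta: float
    split_prob: float
    order: str
    trace: list[dict] = field(default_factory=list)


def _split(grouping: Grouping, rng: np.random.Generator) -> Grouping:
    """Split a uniformly chosen group (>= 2 members) by fair coin per member,
    redrawing until both halves are non-empty."""
    splittable = [i for i, g in enumerate(grouping.groups) if len(g) >= 2]
    gi = splittable[rng.integers(len(splittable))]
    members = sorted(grouping.groups[gi])
    while True:
        coin = rng.integers(2, size=len(members)).astype(bool)
        if coin.any() and not coin.all():
            break
    part = [m for m, c in zip(members, coin) if c]
    return grouping.split(gi, part)


def _merge(grouping: Grouping, rng: np.random.Generator) -> Grouping:
    """Merge a uniformly chosen unordered pair of groups."""
    i, j = rng.choice(grouping.k, size=2, replace=False)
    return grouping.merge(int(i), int(j))


def propose_move(
    state: MetropolisState, rng: np.random.Generator
) -> tuple[int, Grouping]:
    """Draw one candidate move; returns ``(k_source, proposed grouping)``.

    The proposal has ``k' = k_source +- 1`` groups and is always a valid
    partition.
    """
    k = int(rng.integers(state.k_max)) + 1
    grouping = state.groupings[k - 1]
    n_species = grouping.n_species
    if k == 1:
        move = "split"
    elif k == state.k_max:
        move = "merge"
    else:
        move = "split" if rng.random() < state.split_prob else "merge"
    if move == "split" and k == n_species:  # all singletons: nothing to split
        move = "merge"
    new = _split(grouping, rng) if move == "split" else _merge(grouping, rng)
    return k, new


class MetropolisGrouper(BaseEstimator):
    """Partition-space Metropolis search returning one grouping per k.

    Parameters
    ----------
    k_max : largest group count tracked (capped at the species count).
    n_steps : number of main-loop proposals (M).
    beta : inverse temperature; ``inf`` (default) accepts only non-worsening
        moves, with ties accepted.
    split_prob : probability of proposing a split at interior k.
    order : "linear" or "quadratic" regression of function on group
        abundances.
    n_groups : if set, ``labels_``/``grouping_``/``model_`` expose the
        candidate with this many groups after fitting.

    Fitted attributes
    -----------------
    groupings_ : list of the best grouping found for each k = 1..k_max.
    energies_ : their regression RMSEs.
    models_ : the fitted regression models.
    trace_ : per-step record (k proposed, energy, accepted) for diagnostics.
    """

    def __init__(
        self,
        k_max: int = 20,
        n_steps: int = 10000,
        beta: float = np.inf,
        split_prob: float = 0.5,
        order: str = "linear",
        n_groups: int | None = None,
        random_state=None,
    ):
        self.k_max = k_max
        self.n_steps = n_steps
        self.beta = beta
        self.split_prob = split_prob
        self.order = order
        self.n_groups = n_groups
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n_samples, S) with matching y")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        n, S = X.shape
        k_max = min(self.k_max, S)
        if k_max < 2:
            raise ValueError("k_max must be at least 2")
        rng = child_rng(self.random_state, 40)

        groupings = [random_grouping(S, k, rng) for k in range(1, k_max + 1)]
        T_cache = [group_abundances(X, g) for g in groupings]
        models = [fit_group_regression(T, y, order=self.order) for T in T_cache]
        energies = np.array([m.rmse for m in models])
        state = MetropolisState(
            groupings=groupings,
            energies=energies,
            models=models,
            k_max=k_max,
            beta=self.beta,
            split_prob=self.split_prob,
            order=self.order,
        )

        for step in range(self.n_steps):
            _, proposal = propose_move(state, rng)
            kp = proposal.k
            T = group_abundances(X, proposal)
            model = fit_group_regression(T, y, order=self.order)
            e_new, e_old = model.rmse, state.energies[kp - 1]
            if np.isinf(state.beta):
                accept = e_new <= e_old
            else:
                accept = rng.random() < min(1.0, np.exp(-state.beta * (e_new - e_old)))
            if accept:
                state.groupings[kp - 1] = proposal
                state.models[kp - 1] = model
                state.energies[kp - 1] = e_new
            state.trace.append(
                {
                    "step": step,
                    "k": kp,
                    "energy": e_new,
                    "accepted": bool(accept),
                    "stored_energy": float(state.energies[kp - 1]),
                }
            )

        self.state_ = state
        self.groupings_ = state.groupings
        self.energies_ = state.energies
        self.models_ = state.models
        self.trace_ = state.trace
        if self.n_groups is not None:
            self.grouping_ = self.grouping(self.n_groups)
            self.labels_ = self.grouping_.to_labels()
            self.model_ = self.model(self.n_groups)
        return self

    def grouping(self, n_groups: int) -> Grouping:
        """The stored candidate with ``n_groups`` groups."""
        if not 1 <= n_groups <= len(self.groupings_):
            raise ValueError(f"no stored grouping with k={n_groups}")
        return self.groupings_[n_groups - 1]

    def model(self, n_groups: int) -> GroupRegressionModel:
        if not 1 <= n_groups <= len(self.models_):
            raise ValueError(f"no stored model with k={n_groups}")
        return self.models_[n_groups - 1]

    def predict(self, X, n_groups: int | None = None):
        """Predict the function from abundances via the k-group model."""
        k = n_groups if n_groups is not None else self.n_groups
        if k is None:
            raise ValueError("specify n_groups (none was set at construction)")
        X = np.asarray(X, dtype=float)
        T = group_abundances(X, self.grouping(k))
        return self.model(k).predict(T)


def metropolis_fit(dataset, **options):
    """Run the Metropolis search on a dataset.

    Returns ``(groupings, models, trace)`` with one entry per
    ``k = 1..k_max``.
    """
    est = MetropolisGrouper(**options).fit(dataset.abundance, dataset.function)
    return est.groupings_, est.models_, est.trace_
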