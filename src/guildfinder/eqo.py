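"""EQO: Boolean-regression selection of a functional species subset.

EQO poses functional-group discovery as best-subset selection: find the
Boolean vector ``x`` over species whose summed abundance
``f_a = sum_mu A_a_mu x_mu`` best predicts the function through a
1-predictor linear regression, with subset size penalized through
``AIC(x) = 2 kappa + n log(RSS/n)``.  The search over Boolean vectors uses
a genetic algorithm (tournament selection, uniform crossover, per-bit
mutation, elitism) with the stall/stop controls of the original
formulation.  The output is always a 2-group partition: the selected
"functional" group versus everything else.

The EQO-2g variant relaxes the assumption that only the selected group
affects the function: both group abundances enter the regression (two
predictors plus intercept), so e.g. suppression of the function by
competing "nonfunctional" species can be captured.  Its complexity penalty
uses the size of the smaller group, penalizing the selected structure
symmetrically (a convention of this package; the variant's original
description does not fix one).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._rng import child_rng
from .partition import Grouping
from .regression import fit_group_regression, group_abundances

__all__ = ["EQOGrouper", "EQO2GGrouper", "eqo_fit", "eqo2g_fit", "ga_minimize"]


def ga_minimize(
    objective,
    n_bits: int,
    rng: np.random.Generator,
    population_size: int = 100,
    max_generations: int = 10000,
    max_stall_generations: int = 500,
    function_tolerance: float = 1e-9,
    crossover_rate: float = 0.8,
    mutation_rate: float | None = None,
    n_elite: int = 2,
    n_immigrants: int = 10,
):
    """Minimize a set function over Boolean vectors with a genetic algorithm.

    ``objective`` maps a ``(P, n_bits)`` Boolean population to a length-``P``
    float array (``inf`` marks invalid candidates).  Stops when the best
    value has improved by less than ``function_tolerance`` over the last
    ``max_stall_generations`` generations, or at ``max_generations``.

    Besides tournament selection, uniform crossover and per-bit mutation,
    each generation receives ``n_immigrants`` fresh random candidates.
    Without them the population can collapse into a suboptimal basin (e.g.
    the complement of the functional group, which is anti-correlated with
    the function) that per-bit mutation alone cannot escape.

    Returns ``(best_vector, best_value, n_generations)``.
    """
    if mutation_rate is None:
        mutation_rate = 1.0 / n_bits
    pop = rng.random((population_size, n_bits)) < 0.5
    fitness = objective(pop)
    best_idx = int(np.argmin(fitness))
    best_x, best_val = pop[best_idx].copy(), float(fitness[best_idx])
    stall_val, stall = best_val, 0

    gen = 0
    for gen in range(1, max_generations + 1):
        # tournament selection (size 2) of parents
        draws = rng.integers(population_size, size=(2, 2 * population_size))
        winners = np.where(
            fitness[draws[0]] <= fitness[draws[1]], draws[0], draws[1]
        )
        parents = pop[winners].reshape(2, population_size, n_bits)
        # uniform crossover
        cross = rng.random(population_size) < crossover_rate
        mask = rng.random((population_size, n_bits)) < 0.5
        children = np.where(mask, parents[0], parents[1])
        children[~cross] = parents[0][~cross]
        # per-bit mutation
        children ^= rng.random((population_size, n_bits)) < mutation_rate
        # fresh random immigrants keep the search global
        if n_immigrants:
            children[n_elite : n_elite + n_immigrants] = (
                rng.random((n_immigrants, n_bits)) < 0.5
            )
        # elitism: keep the best of the current population
        elite_idx = np.argsort(fitness)[:n_elite]
        children[:n_elite] = pop[elite_idx]
        pop = children
        fitness = objective(pop)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_val:
            best_x, best_val = pop[gen_best].copy(), float(fitness[gen_best])
        # stall detection on the running best
        if stall_val - best_val > function_tolerance:
            stall_val, stall = best_val, 0
        else:
            stall += 1
            if stall >= max_stall_generations:
                break
    return best_x, best_val, gen


def _eqo_objective(A: np.ndarray, y: np.ndarray):
    """Vectorized AIC of the 1-predictor regression of y on f = A x.

    Evaluates a whole Boolean population at once; all-zero candidates are
    invalid and receive +inf without being evaluated.
    """
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)

    def objective(pop: np.ndarray) -> np.ndarray:
        kappa = pop.sum(axis=1)
        valid = kappa > 0
        out = np.full(len(pop), np.inf)
        if not valid.any():
            return out
        f = A @ pop[valid].astype(float).T  # (n, P_valid)
        fc = f - f.mean(axis=0)
        sff = np.einsum("np,np->p", fc, fc)
        sfy = yc @ fc
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = syy - np.where(sff > 0, sfy**2 / np.where(sff > 0, sff, 1.0), 0.0)
        rss = np.maximum(rss, 0.0)
        with np.errstate(divide="ignore"):
            aic = 2.0 * kappa[valid] + n * np.log(np.maximum(rss, 0.0) / n)
        out[valid] = np.where(rss == 0, -np.inf, aic)
        return out

    return objective


def _eqo2g_objective(A: np.ndarray, y: np.ndarray):
    """Vectorized AIC of the 2-predictor regression on both group abundances.

    Predictors are ``f = A x`` and ``A (1 - x)``; kappa is the size of the
    smaller group.  All-zero and all-one candidates are invalid.
    """
    n, S = A.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    total = A.sum(axis=1)

    def objective(pop: np.ndarray) -> np.ndarray:
        kappa_sel = pop.sum(axis=1)
        valid = (kappa_sel > 0) & (kappa_sel < S)
        out = np.full(len(pop), np.inf)
        if not valid.any():
            return out
        f1 = A @ pop[valid].astype(float).T
        f2 = total[:, None] - f1
        c1 = f1 - f1.mean(axis=0)
        c2 = f2 - f2.mean(axis=0)
        s11 = np.einsum("np,np->p", c1, c1)
        s22 = np.einsum("np,np->p", c2, c2)
        s12 = np.einsum("np,np->p", c1, c2)
        s1y = yc @ c1
        s2y = yc @ c2
        det = s11 * s22 - s12**2
        scale = np.maximum(s11 * s22, 1e-300)
        ok = det > 1e-12 * scale
        b1 = np.where(ok, (s22 * s1y - s12 * s2y) / np.where(ok, det, 1.0), 0.0)
        b2 = np.where(ok, (s11 * s2y - s12 * s1y) / np.where(ok, det, 1.0), 0.0)
        rss = syy - b1 * s1y - b2 * s2y
        # near-collinear predictors: fall back to the better single predictor
        rss1 = syy - np.where(s11 > 0, s1y**2 / np.where(s11 > 0, s11, 1.0), 0.0)
        rss2 = syy - np.where(s22 > 0, s2y**2 / np.where(s22 > 0, s22, 1.0), 0.0)
        rss = np.where(ok, rss, np.minimum(rss1, rss2))
        rss = np.maximum(rss, 0.0)
        kappa = np.minimum(kappa_sel[valid], S - kappa_sel[valid])
        with np.errstate(divide="ignore"):
            aic = 2.0 * kappa + n * np.log(np.maximum(rss, 0.0) / n)
        out[valid] = np.where(rss == 0, -np.inf, aic)
        return out

    return objective


class _BaseEQO(BaseEstimator):
    def __init__(
        self,
        population_size=100,
        max_generations=10000,
        max_stall_generations=500,
        function_tolerance=1e-9,
        crossover_rate=0.8,
        mutation_rate=None,
        n_elite=2,
        n_immigrants=10,
        random_state=None,
    ):
        self.population_size = population_size
        self.max_generations = max_generations
        self.max_stall_generations = max_stall_generations
        self.function_tolerance = function_tolerance
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.n_elite = n_elite
        self.n_immigrants = n_immigrants
        self.random_state = random_state

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D abundance table")
        if y.shape != (X.shape[0],):
            raise ValueError("y must have one value per sample")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        return X, y

    def _search(self, X, y, objective):
        rng = child_rng(self.random_state, 20)
        return ga_minimize(
            objective,
            n_bits=X.shape[1],
            rng=rng,
            population_size=self.population_size,
            max_generations=self.max_generations,
            max_stall_generations=self.max_stall_generations,
            function_tolerance=self.function_tolerance,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            n_elite=self.n_elite,
            n_immigrants=self.n_immigrants,
        )


class EQOGrouper(_BaseEQO):
    """Select the species subset whose summed abundance best predicts y.

    Fitted attributes
    -----------------
    selection_ : Boolean species mask of the functional group.
    labels_ : 0 for selected species, 1 for the rest.
    grouping_ : the induced 2-group :class:`Grouping`.
    model_ : 1-predictor regression of y on the selected group abundance.
    aic_ : AIC of the returned selection.
    n_generations_ : generations run by the genetic search.
    """

    def fit(self, X, y):
        X, y = self._validate(X, y)
        objective = _eqo_objective(X, y)
        best, aic, gens = self._search(X, y, objective)
        self.selection_ = best
        self.aic_ = aic
        self.n_generations_ = gens
        labels = np.where(best, 0, 1)
        if labels.max() == 0 or labels.min() == 1:  # one group empty
            self.grouping_ = Grouping.from_labels(np.zeros(len(best), dtype=int))
        else:
            self.grouping_ = Grouping.from_labels(labels)
        self.labels_ = labels
        f = (X @ best.astype(float))[:, None]
        self.model_ = fit_group_regression(f, y, order="linear")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.model_.predict((X @ self.selection_.astype(float))[:, None])


class EQO2GGrouper(_BaseEQO):
    """EQO variant in which both groups' abundances predict the function."""

    def fit(self, X, y):
        X, y = self._validate(X, y)
        objective = _eqo2g_objective(X, y)
        best, aic, gens = self._search(X, y, objective)
        self.selection_ = best
        self.aic_ = aic
        self.n_generations_ = gens
        self.labels_ = np.where(best, 0, 1)
        self.grouping_ = Grouping.from_labels(self.labels_)
        T = group_abundances(X, self.grouping_)
        self.model_ = fit_group_regression(T, y, order="linear")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.model_.predict(group_abundances(X, self.grouping_))


def eqo_fit(dataset, **options):
    """Run EQO on a dataset; returns ``(selection, grouping, model)``."""
    est = EQOGrouper(**options).fit(dataset.abundance, dataset.function)
    return est.selection_, est.grouping_, est.model_


def eqo2g_fit(dataset, **options):
    """Run the two-group EQO variant; returns ``(grouping, model)``."""
    est = EQO2GGrouper(**options).fit(dataset.abundance, dataset.function)
    return est.grouping_, est.model_
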