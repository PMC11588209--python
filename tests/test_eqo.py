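import itertools

import numpy as np
import pytest

from guildfinder import (
    EQO2GGrouper,
    EQOGrouper,
    aic_score,
    eqo_fit,
    fit_group_regression,
    generate_dataset,
    generate_pool,
    linear_chain,
)
from guildfinder.eqo import _eqo2g_objective, _eqo_objective
from guildfinder.pool import GeneralizedResources


def brute_force_eqo(A, y):
    """Exhaustive minimum of the subset-selection AIC over all non-empty
    selections; independent of the genetic search."""
    n, S = A.shape
    best_val, best_x = np.inf, None
    for bits in itertools.product([0, 1], repeat=S):
        x = np.array(bits, dtype=bool)
        if not x.any():
            continue
        f = A @ x.astype(float)
        model = fit_group_regression(f[:, None], y, "linear")
        val = aic_score(int(x.sum()), n, model.rss)
        if val < best_val:
            best_val, best_x = val, x
    return best_x, best_val


def brute_force_eqo2g(A, y):
    """Exhaustive minimum of the 2-group objective (both groups predict,
    kappa = smaller group size) over all 2-group partitions."""
    n, S = A.shape
    best_val, best_x = np.inf, None
    for bits in itertools.product([0, 1], repeat=S):
        x = np.array(bits, dtype=bool)
        if not x.any() or x.all():
            continue
        T = np.stack([A @ x, A @ ~x], axis=1)
        model = fit_group_regression(T, y, "linear")
        val = aic_score(int(min(x.sum(), S - x.sum())), n, model.rss)
        if val < best_val:
            best_val, best_x = val, x
    return best_x, best_val


class TestObjectives:
    def test_vectorized_objective_matches_bruteforce_fit(self, toy_table):
        A, y = toy_table
        objective = _eqo_objective(A, y)
        pop = np.array(list(itertools.product([0, 1], repeat=6)), dtype=bool)
        vals = objective(pop)
        assert vals[0] == np.inf  # all-zero candidate is invalid
        for x, val in zip(pop[1:], vals[1:]):
            f = A @ x.astype(float)
            model = fit_group_regression(f[:, None], y, "linear")
            expected = aic_score(int(x.sum()), len(y), model.rss)
            assert val == pytest.approx(expected, rel=1e-9)

    def test_2g_objective_matches_bruteforce_fit(self, toy_table):
        A, y = toy_table
        objective = _eqo2g_objective(A, y)
        pop = np.array(list(itertools.product([0, 1], repeat=6)), dtype=bool)
        vals = objective(pop)
        assert vals[0] == np.inf and vals[-1] == np.inf
        for x, val in zip(pop[1:-1], vals[1:-1]):
            T = np.stack([A @ x, A @ ~x], axis=1)
            model = fit_group_regression(T, y, "linear")
            expected = aic_score(int(min(x.sum(), 6 - x.sum())), len(y), model.rss)
            assert val == pytest.approx(expected, rel=1e-9)


class TestEQOGrouper:
    def test_attains_exhaustive_minimum(self, toy_table):
        A, y = toy_table
        _, best_val = brute_force_eqo(A, y)
        est = EQOGrouper(random_state=0).fit(A, y)
        assert est.aic_ == pytest.approx(best_val, rel=1e-9)

    def test_recovers_planted_group(self, toy_table):
        A, y = toy_table  # y is driven by species {0, 1}
        est = EQOGrouper(random_state=0).fit(A, y)
        assert set(np.flatnonzero(est.selection_)) == {0, 1}
        assert est.grouping_.k == 2

    def test_selects_direct_producers_on_noiseless_chain(self):
        """On clean two-step-chain data the optimal selection is exactly the
        functional group, verified against the exhaustive optimum."""
        topo = linear_chain(2)
        pool = generate_pool(10, topo, GeneralizedResources(n_resources=6), seed=21)
        ds = generate_dataset(pool, 120, subset_size=5, noise=0.0, seed=22)
        best_x, best_val = brute_force_eqo(ds.abundance, ds.function)
        est = EQOGrouper(random_state=1).fit(ds.abundance, ds.function)
        assert est.aic_ == pytest.approx(best_val, rel=1e-9)
        functional = set(np.flatnonzero(pool.truth.to_labels() == 0))
        assert set(np.flatnonzero(best_x)) == functional
        assert set(np.flatnonzero(est.selection_)) == functional

    def test_result_equivariant_under_column_permutation(self, toy_table):
        A, y = toy_table
        perm = np.array([3, 0, 5, 1, 4, 2])  # column j of A2 is species perm[j]
        est = EQOGrouper(random_state=0).fit(A, y)
        est_p = EQOGrouper(random_state=0).fit(A[:, perm], y)
        assert set(perm[np.flatnonzero(est_p.selection_)]) == set(
            np.flatnonzero(est.selection_)
        )

    def test_predict_matches_model(self, toy_table):
        A, y = toy_table
        est = EQOGrouper(random_state=0).fit(A, y)
        np.testing.assert_allclose(
            est.predict(A), est.model_.predict((A @ est.selection_)[:, None])
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            EQOGrouper().fit(np.ones((1, 3)), np.ones(1))
        with pytest.raises(ValueError):
            EQOGrouper().fit(np.ones((4, 3)), np.ones(5))


class TestEQO2GGrouper:
    def test_attains_exhaustive_minimum(self, toy_table):
        A, y = toy_table
        _, best_val = brute_force_eqo2g(A, y)
        est = EQO2GGrouper(random_state=0).fit(A, y)
        assert est.aic_ == pytest.approx(best_val, rel=1e-9)
        assert est.grouping_.k == 2

    def test_two_predictor_objective_dominates_single(self, toy_table):
        """Adding the complement group as a second predictor can only lower
        the optimal objective (nested least squares, smaller penalty)."""
        A, y = toy_table
        _, val_eqo = brute_force_eqo(A, y)
        _, val_2g = brute_force_eqo2g(A, y)
        assert val_2g <= val_eqo + 1e-12

    def test_ga_matches_both_bruteforce_optima(self, toy_table):
        A, y = toy_table
        est1 = EQOGrouper(random_state=3).fit(A, y)
        est2 = EQO2GGrouper(random_state=3).fit(A, y)
        assert est2.aic_ <= est1.aic_ + 1e-12


def test_functional_wrappers(toy_table):
    A, y = toy_table

    class _DS:
        abundance, function = A, y

    selection, grouping, model = eqo_fit(_DS, random_state=0)
    assert grouping.k == 2 and selection.dtype == bool and model.rmse >= 0
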