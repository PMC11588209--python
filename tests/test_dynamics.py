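import numpy as np
import pytest

from guildfinder import (
    CommunityState,
    GeneralizedResources,
    Grouping,
    SolverOptions,
    SpeciesPool,
    closed_form_function,
    dynamics_rhs,
    equilibrate,
    equilibrate_batch,
    linear_chain,
    resource_availability,
)


def reference_rhs(n, m, pool):
    """Independently written scalar-loop implementation of the dynamics,
    used as a duplicate-implementation oracle."""
    topo = pool.topology
    S, N = pool.tau.shape
    H = pool.resources.n_resources
    h = np.empty(H)
    for a in range(H):
        expl = sum(pool.sigma[nu, a] * n[nu] for nu in range(S))
        h[a] = pool.resources.max_benefit / (1 + expl / pool.resources.half_saturation)
    g = topo.retained_fraction
    dn = np.empty(S)
    for mu in range(S):
        growth = -pool.chi[mu]
        for i in range(N):
            growth += g[i] * pool.tau[mu, i] * m[i]
        for a in range(H):
            growth += pool.sigma[mu, a] * h[a]
        dn[mu] = n[mu] * growth
    dm = np.empty(N)
    for i in range(N):
        T_i = sum(pool.tau[mu, i] * n[mu] for mu in range(S))
        dm[i] = topo.supply[i] - m[i] * T_i - topo.decay[i] * m[i]
    for src, dst, w in topo.edges:
        T_src = sum(pool.tau[mu, src] * n[mu] for mu in range(S))
        dm[dst] += w * m[src] * T_src
    return dn, dm


class TestResourceAvailability:
    def test_unexploited_resource_gives_full_benefit(self, pool48):
        h = resource_availability(pool48, np.zeros(48))
        np.testing.assert_allclose(h, 3.0)

    def test_half_saturation(self):
        """Total exploitation of 2 with K = 1 cuts h0 = 3 down to 1."""
        topo = linear_chain(2)
        pool = SpeciesPool(
            topology=topo,
            resources=GeneralizedResources(n_resources=1),
            tau=np.array([[1.0, 0.0]]),
            sigma=np.array([[1.0]]),
            chi=np.zeros(1),
            cost_noise=0.0,
            cost_draws=np.zeros(1),
            truth=Grouping.from_labels([0]),
        )
        assert resource_availability(pool, [2.0])[0] == pytest.approx(1.0)

    def test_vanishes_at_high_exploitation(self, pool48):
        h = resource_availability(pool48, np.full(48, 1e9))
        assert (h < 1e-6).all()

    def test_negative_abundance_rejected(self, pool48):
        with pytest.raises(ValueError):
            resource_availability(pool48, np.full(48, -1.0))


class TestDynamicsRhs:
    def test_no_consumers_metabolite_balance(self, pool48):
        m = np.array([2.5, 0.0, 0.0])
        _, dm = dynamics_rhs(np.zeros(48), m, pool48)
        # dm_0 = R_0 - d_0 m_0 with no consumption
        assert dm[0] == pytest.approx(4.0 - 2.5)
        np.testing.assert_allclose(dm[1:], 0.0)

    def test_balanced_single_species(self):
        """Benefit (1 - w) tau m = 0.5 exactly cancels cost chi = 0.5."""
        topo = linear_chain(2)
        pool = SpeciesPool(
            topology=topo,
            resources=GeneralizedResources(n_resources=0),
            tau=np.array([[1.0, 0.0]]),
            sigma=np.zeros((1, 0)),
            chi=np.array([0.5]),
            cost_noise=0.0,
            cost_draws=np.zeros(1),
            truth=Grouping.from_labels([0]),
        )
        dn, _ = dynamics_rhs(np.ones(1), np.array([1.0, 0.0]), pool)
        assert dn[0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_independent_implementation(self, pool48):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = rng.gamma(1.0, 1.0, size=48)
            m = rng.gamma(1.0, 1.0, size=3)
            dn, dm = dynamics_rhs(n, m, pool48)
            dn_ref, dm_ref = reference_rhs(n, m, pool48)
            np.testing.assert_allclose(dn, dn_ref, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(dm, dm_ref, rtol=1e-12, atol=1e-12)

    def test_dimension_mismatch(self, pool48):
        with pytest.raises(ValueError):
            dynamics_rhs(np.zeros(10), np.zeros(3), pool48)


class TestEquilibrate:
    def test_empty_community_fixed_point(self, pool48):
        state = equilibrate(pool48, [])
        np.testing.assert_allclose(state.m, [4.0, 0.0, 0.0])
        dn, dm = dynamics_rhs(state.n, state.m, pool48)
        assert np.abs(np.concatenate([dn, dm])).max() < 1e-12

    def test_converged_state_is_stationary(self, pool48):
        state = equilibrate(pool48, range(15))
        assert state.converged
        dn, dm = dynamics_rhs(state.n, state.m, pool48)
        z = np.concatenate([state.n[state.members], state.m])
        resid = np.abs(np.concatenate([dn[state.members], dm])) / (np.abs(z) + 1)
        assert resid.max() < 1e-6

    def test_non_members_stay_absent(self, pool48):
        members = [0, 5, 17, 30, 40]
        state = equilibrate(pool48, members)
        outside = np.setdiff1d(np.arange(48), members)
        assert (state.n[outside] == 0).all()
        assert (state.n >= 0).all() and (state.m >= 0).all()

    def test_batch_matches_closed_form(self, pool48):
        """ODE equilibrium end product vs the analytic expression at the
        realized group abundances, on random member sets."""
        rng = np.random.default_rng(1)
        members = np.stack([rng.choice(48, 15, replace=False) for _ in range(8)])
        states = equilibrate_batch(pool48, members)
        for st in states:
            T = pool48.tau.T @ st.n
            if (T[:2] < 1e-3).any():
                continue  # absent group: both sides ~ 0
            pred = closed_form_function(T[:2], pool48.topology)
            assert abs(st.m[2] - pred) / pred < 1e-3

    def test_member_index_validation(self, pool48):
        with pytest.raises(ValueError):
            equilibrate(pool48, [48])

    def test_nonconvergence_handling(self, pool48):
        opts = SolverOptions(max_time=1.0, window=1.0)  # far too short
        with pytest.raises(RuntimeError):
            equilibrate_batch(pool48, np.arange(15)[None, :],
                              SolverOptions(max_time=1.0, window=1.0, on_nonconverged="error"))
        states = equilibrate_batch(pool48, np.arange(15)[None, :], opts)
        assert not states[0].converged
        assert equilibrate_batch(
            pool48, np.arange(15)[None, :],
            SolverOptions(max_time=1.0, window=1.0, on_nonconverged="drop"),
        ) == []


class TestClosedForm:
    def test_absent_group_kills_function(self, chain3):
        assert closed_form_function([0.0, 10.0], chain3) == 0.0

    def test_worked_example(self, chain3):
        # R1 = 4, w = 0.5, d = 1, T = (16, 16): 4 * (8/17)^2 = 256/289
        val = closed_form_function([16.0, 16.0], chain3)
        assert val == pytest.approx(256 / 289)

    def test_saturates_at_unity(self, chain3):
        assert closed_form_function([1e12, 1e12], chain3) == pytest.approx(1.0, rel=1e-9)

    def test_requires_chain(self):
        from guildfinder import custom_topology

        topo = custom_topology(
            edges=[(0, 2, 0.5), (1, 2, 0.5)],
            supply=[2.0, 2.0, 0.0],
            decay=[1.0, 1.0, 1.0],
            function_index=2,
        )
        with pytest.raises(ValueError):
            closed_form_function([1.0, 1.0], topo)

    def test_vectorized(self, chain3):
        T = np.array([[16.0, 16.0], [0.0, 5.0]])
        out = closed_form_function(T, chain3)
        assert out.shape == (2,)
        assert out[1] == 0.0
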