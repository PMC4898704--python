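"""Master-equation solver against enumeration, quadrature and closed forms."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import binom

from titinsim.errors import ConfigError, ValidationError
from titinsim.kinetics import Cluster, ClusterModel, RefoldingParams
from titinsim.exact import (
    ClusterStateSpace,
    StateProbabilities,
    aggregate,
    expected_force,
    first_unfolding_distribution,
    generator_matrix,
    solve_master,
    solve_master_with_refolding,
)
from titinsim.montecarlo import simulate_ensemble

from conftest import flat_family, hold


def const_model(rates, sizes, refolding=None):
    """Clusters with force-independent rates (x_u = 0)."""
    return ClusterModel(tuple(Cluster(n, w) for n, w in zip(sizes, rates)),
                        x_u=0.0, refolding=refolding)


class TestStateSpace:
    def test_enumeration_counts(self):
        space = ClusterStateSpace([2, 3])
        assert space.n_states == 12
        assert [space.level_size(l) for l in range(6)] == [1, 2, 3, 3, 2, 1]

    def test_index_round_trip(self):
        space = ClusterStateSpace([3, 2, 4])
        for state in ([0, 0, 0], [3, 2, 4], [1, 2, 3]):
            idx = space.index_of(state)
            assert list(space.states[idx]) == state

    def test_bounds(self):
        space = ClusterStateSpace([2, 2])
        with pytest.raises(ValidationError):
            space.index_of([3, 0])


class TestGenerator:
    def test_columns_sum_to_zero(self):
        space = ClusterStateSpace([2, 3])
        model = const_model([0.7, 1.9], [2, 3])
        A = generator_matrix(space, model, np.full(6, 5e-12))
        assert np.abs(np.asarray(A.sum(axis=0))).max() < 1e-14
        with_ref = const_model([0.7, 1.9], [2, 3],
                               refolding=RefoldingParams(omega1=1.1,
                                                         x_f=0.0))
        A = generator_matrix(space, with_ref, np.full(6, 5e-12))
        assert np.abs(np.asarray(A.sum(axis=0))).max() < 1e-14

    def test_fully_unfolded_state_is_absorbing(self):
        space = ClusterStateSpace([2, 3])
        model = const_model([0.7, 1.9], [2, 3])
        A = generator_matrix(space, model, np.full(6, 5e-12)).toarray()
        absorbing = space.index_of([2, 3])
        assert np.all(A[:, absorbing] == 0.0)

    def test_three_state_chain_matches_hand_written_matrix(self):
        # one cluster of two domains at constant rate u: states 0,1,2
        u = 1.3
        space = ClusterStateSpace([2])
        model = const_model([u], [2])
        A = generator_matrix(space, model, np.full(3, 1e-12)).toarray()
        expected = np.array([[-2 * u, 0.0, 0.0],
                             [2 * u, -u, 0.0],
                             [0.0, u, 0.0]])
        assert np.allclose(A, expected, rtol=1e-12)

    def test_mismatched_force_vector_rejected(self):
        space = ClusterStateSpace([2, 3])
        model = const_model([0.7, 1.9], [2, 3])
        with pytest.raises(ConfigError):
            generator_matrix(space, model, np.full(4, 1e-12))


class TestSolveMaster:
    def test_zero_rates_keep_the_folded_delta(self):
        model = const_model([0.0, 0.0], [2, 2])
        fam = flat_family(np.full(5, 5e-12))
        sol = solve_master(hold(1.0), model, fam, dt=1e-2)
        assert np.all(sol.aggregated[:, 0] == 1.0)
        assert np.all(sol.aggregated[:, 1:] == 0.0)

    def test_single_cluster_survival_converges_first_order(self):
        n, u, t_end = 3, 2.0, 0.5
        model = const_model([u], [n])
        fam = flat_family(np.full(n + 1, 5e-12))
        exact = np.exp(-n * u * t_end)
        errs = []
        for dt in (4e-3, 2e-3, 1e-3):
            sol = solve_master(hold(t_end), model, fam, dt=dt)
            errs.append(abs(sol.aggregated[-1, 0] - exact))
        ratios = np.array(errs[:-1]) / np.array(errs[1:])
        assert np.all((ratios > 1.7) & (ratios < 2.3))

    def test_probability_conservation_and_nonnegativity(self, family,
                                                        default_model, ramp):
        sol = solve_master(ramp, default_model, family, dt=1e-3)
        assert sol.renormalizations == 0
        sums = sol.aggregated.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-9
        assert sol.aggregated.min() >= -1e-10
        assert np.all(np.diff(sol.aggregated[:, 0]) <= 1e-15)

    def test_two_cluster_quadrature_oracle_for_p0_p1(self):
        # Independent oracle: direct quadrature of the survival integral
        # and the one-event path integral at constant rates.  The
        # backward-Euler output is step-doubling (Richardson)
        # extrapolated, cancelling its leading O(dt) bias.
        n1, n2, u1, u2 = 2, 3, 0.8, 2.1
        t_end = 0.1
        model = const_model([u1, u2], [n1, n2])
        fam = flat_family(np.full(6, 5e-12))
        prot = hold(t_end)
        sol_a = solve_master(prot, model, fam, dt=2e-5)
        sol_b = solve_master(prot, model, fam, dt=1e-5)
        agg = 2 * sol_b.aggregated[-1] - sol_a.aggregated[-1]
        h0 = n1 * u1 + n2 * u2
        p0 = np.exp(-h0 * t_end)

        def p1_integrand(tau, which):
            surv_before = np.exp(-h0 * tau)
            if which == 1:
                rate, after = n1 * u1, (n1 - 1) * u1 + n2 * u2
            else:
                rate, after = n2 * u2, n1 * u1 + (n2 - 1) * u2
            return surv_before * rate * np.exp(-after * (t_end - tau))

        p1 = sum(quad(p1_integrand, 0, t_end, args=(w,), epsabs=1e-14)[0]
                 for w in (1, 2))
        assert agg[0] == pytest.approx(p0, rel=1e-6)
        assert agg[1] == pytest.approx(p1, rel=1e-6)

    def test_matches_matrix_exponential_at_frozen_force(self):
        # step-doubling extrapolation of the backward-Euler solution
        # converges to the matrix-exponential propagator on every state
        sizes = [2, 3]
        model = const_model([0.9, 2.4], sizes)
        fam = flat_family(np.full(6, 5e-12))
        t_end = 0.1
        prot = hold(t_end)
        sol_a = solve_master(prot, model, fam, dt=2e-5)
        sol_b = solve_master(prot, model, fam, dt=1e-5)
        p_ext = 2 * sol_b.final.p - sol_a.final.p
        space = sol_a.space
        A = generator_matrix(space, model, np.full(6, 5e-12)).toarray()
        p0 = np.zeros(space.n_states)
        p0[0] = 1.0
        pT = expm(A * t_end) @ p0
        assert np.allclose(p_ext, pT, rtol=1e-6, atol=1e-12)
        # the raw first-order solution is accurate to its error model
        assert np.allclose(sol_b.final.p, pT, rtol=5e-3, atol=1e-12)

    def test_agrees_with_monte_carlo_histogram(self):
        sizes = [2, 3]
        model = const_model([3.0, 8.0], sizes)
        fam = flat_family(np.full(6, 5e-12))
        prot = hold(0.1)
        sol = solve_master(prot, model, fam, dt=1e-5)
        res = simulate_ensemble(prot, 10_000, model, fam, dt=1e-4, seed=21)
        hist = np.bincount(res.final_unfolded, minlength=6) / 10_000
        tv = 0.5 * np.abs(hist - sol.aggregated[-1]).sum()
        assert tv < 0.05


class TestAggregateAndExpectation:
    def test_initial_delta_aggregates_to_level_zero(self):
        space = ClusterStateSpace([2, 2])
        p = np.zeros(space.n_states)
        p[space.index_of([0, 0])] = 1.0
        agg = aggregate(StateProbabilities(space, p, 0.0))
        assert agg[0] == 1.0 and agg[1:].sum() == 0.0

    def test_single_cluster_aggregation_is_identity(self):
        space = ClusterStateSpace([4])
        p = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        agg = aggregate(StateProbabilities(space, p, 0.0))
        assert np.array_equal(agg, p)

    def test_expectation_is_convex_combination(self, family):
        lengths = np.linspace(1.2e-6, 1.9e-6, 40)
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(51), size=40)
        ef = expected_force(P, family, lengths)
        table = family.table(lengths)
        assert np.all(ef <= table.max(axis=1) + 1e-18)
        assert np.all(ef >= table.min(axis=1) - 1e-18)
        # mass concentrated on level 0 reproduces the top curve
        P0 = np.zeros((40, 51))
        P0[:, 0] = 1.0
        assert np.allclose(expected_force(P0, family, lengths),
                           table[:, 0], rtol=1e-12)

    def test_strand_count_scaling(self, family):
        lengths = np.array([1.5e-6, 1.6e-6])
        P = np.zeros((2, 51))
        P[:, 0] = 1.0
        single = expected_force(P, family, lengths)
        scaled = expected_force(P, family, lengths, n_strands=1.2e9)
        assert np.allclose(scaled, 1.2e9 * single, rtol=1e-12)

    def test_grid_mismatch_rejected(self, family):
        with pytest.raises(ValidationError):
            expected_force(np.ones((3, 51)) / 51, family,
                           np.array([1.5e-6, 1.6e-6]))


class TestRefolding:
    def test_pure_refolding_decay(self):
        # omega0 = 0, all domains unfolded initially, constant force:
        # P(all still unfolded at t) = exp(-n r t)
        n, omega1, t_end = 4, 2.0, 0.5
        model = const_model([0.0], [n],
                            refolding=RefoldingParams(omega1=omega1,
                                                      x_f=0.0))
        fam = flat_family(np.full(n + 1, 5e-12))
        sol = solve_master_with_refolding(hold(t_end), model, fam, dt=1e-5,
                                          initial_state=[n])
        expect = np.exp(-n * omega1 * sol.times)
        assert np.allclose(sol.aggregated[:, n], expect, rtol=2e-4)

    def test_stationary_distribution_is_binomial(self):
        # u = r: detailed balance gives Binomial(n, 1/2)
        n = 4
        model = const_model([1.0], [n],
                            refolding=RefoldingParams(omega1=1.0, x_f=0.0))
        fam = flat_family(np.full(n + 1, 5e-12))
        sol = solve_master_with_refolding(hold(30.0), model, fam, dt=1e-3)
        target = binom.pmf(np.arange(n + 1), n, 0.5)
        assert np.allclose(sol.aggregated[-1], target, atol=1e-10)

    def test_multicluster_refolding_matches_matrix_exponential(self):
        sizes = [2, 2]
        model = const_model([0.8, 1.6], sizes,
                            refolding=RefoldingParams(omega1=1.2, x_f=0.0))
        fam = flat_family(np.full(5, 5e-12))
        t_end = 0.2
        sol = solve_master_with_refolding(hold(t_end), model, fam, dt=1e-5)
        space = sol.space
        A = generator_matrix(space, model, np.full(5, 5e-12)).toarray()
        p0 = np.zeros(space.n_states)
        p0[0] = 1.0
        pT = expm(A * t_end) @ p0
        # first-order accuracy at dt = 1e-5 over rates of order 1
        assert np.allclose(sol.final.p, pT, rtol=1e-3, atol=1e-10)

    def test_missing_refolding_params_rejected(self):
        model = const_model([1.0], [3])
        fam = flat_family(np.full(4, 5e-12))
        with pytest.raises(ConfigError):
            solve_master_with_refolding(hold(0.1), model, fam, dt=1e-3)


class TestFirstUnfoldingDensity:
    def test_zero_rates_put_all_mass_on_no_event(self, family, ramp):
        model = const_model([0.0], [50])
        dens = first_unfolding_distribution(model, family, ramp, dt=1e-3)
        assert dens.no_event_mass == pytest.approx(1.0)
        assert np.all(dens.density_time == 0.0)

    def test_density_integrates_to_event_probability(self, family,
                                                     default_model, ramp):
        dens = first_unfolding_distribution(default_model, family, ramp,
                                            dt=1e-4)
        mass = np.trapezoid(dens.density_time, dens.times)
        assert mass == pytest.approx(1.0 - dens.no_event_mass, rel=1e-3)

    def test_constant_force_falls_back_to_time_domain(self, make_hold):
        model = const_model([1.0], [3])
        fam = flat_family(np.full(4, 5e-12))
        dens = first_unfolding_distribution(model, fam, make_hold(0.5),
                                            dt=1e-3)
        assert dens.density_force is None

    def test_refolding_model_rejected(self, family, ramp):
        model = const_model([1.0], [50],
                            refolding=RefoldingParams(omega1=1.0))
        with pytest.raises(ConfigError):
            first_unfolding_distribution(model, family, ramp)
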