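"""Monte Carlo engine: event selection, reproducibility, stochastic oracles."""

import numpy as np
import pytest

from titinsim.errors import TimeStepError, ValidationError
from titinsim.kinetics import (Cluster, ClusterModel, RefoldingParams,
                               single_cluster_model)
from titinsim.montecarlo import (first_unfolding_forces, mce,
                                 simulate_ensemble, step)
from titinsim.protocols import LengthProtocol


class FixedRng:
    """Stub RNG returning a prescribed uniform draw."""

    def __init__(self, z):
        self.z = z

    def random(self, n=None):
        return self.z if n is None else np.full(n, self.z)


def _const_model(rates, sizes=None, refolding=None):
    """Force-independent clusters (x_u = 0) with given event rates."""
    sizes = sizes or [3] * len(rates)
    return ClusterModel(tuple(Cluster(n, w) for n, w in zip(sizes, rates)),
                        x_u=0.0, refolding=refolding)


class TestStep:
    def test_zero_rates_leave_state_unchanged(self, make_flat_family,
                                              make_hold):
        model = _const_model([0.0, 0.0])
        fam = make_flat_family(np.linspace(10e-12, 4e-12, 7))
        prot = make_hold(1.0)
        for z in (0.0, 0.3, 0.999):
            out = step([1, 2], 0.0, 1e-3, FixedRng(z), protocol=prot,
                       model=model, family=fam)
            assert list(out) == [1, 2]

    def test_z_in_cluster_interval_triggers_that_cluster(self,
                                                         make_flat_family,
                                                         make_hold):
        # p_1 = 3*10*dt = 0.03, p_2 = 1*20*dt = 0.02
        model = _const_model([10.0, 20.0], sizes=[3, 1])
        fam = make_flat_family(np.full(5, 5e-12))
        prot = make_hold(1.0)
        cases = [(0.015, [1, 0]), (0.04, [0, 1]), (0.06, [0, 0])]
        for z, expected in cases:
            out = step([0, 0], 0.0, 1e-3, FixedRng(z), protocol=prot,
                       model=model, family=fam)
            assert list(out) == expected

    def test_refolding_interval_follows_unfolding(self, make_flat_family,
                                                  make_hold):
        model = _const_model([10.0], sizes=[2],
                             refolding=RefoldingParams(omega1=30.0, x_f=0.0))
        fam = make_flat_family(np.full(3, 5e-12))
        prot = make_hold(1.0)
        # state [1]: p_unfold = 1*10*dt = 0.01, p_refold = 1*30*dt = 0.03
        out = step([1], 0.0, 1e-3, FixedRng(0.02), protocol=prot,
                   model=model, family=fam)
        assert list(out) == [0]

    def test_excessive_step_probability_raises(self, make_flat_family,
                                               make_hold):
        model = _const_model([500.0])
        fam = make_flat_family(np.full(4, 5e-12))
        with pytest.raises(TimeStepError, match="reduce dt"):
            step([0], 0.0, 1e-3, FixedRng(0.5), protocol=make_hold(1.0),
                 model=model, family=fam)

    def test_state_validation(self, make_flat_family, make_hold):
        model = _const_model([1.0])
        fam = make_flat_family(np.full(4, 5e-12))
        with pytest.raises(ValidationError):
            step([7], 0.0, 1e-3, FixedRng(0.5), protocol=make_hold(1.0),
                 model=model, family=fam)


class TestEnsemble:
    def test_zero_rates_reproduce_top_curve(self, make_flat_family):
        model = _const_model([0.0])
        fam = make_flat_family(np.array([9e-12, 5e-12, 2e-12, 1e-12]))
        prot = LengthProtocol(np.array([0.0, 1.0]), np.array([0.2, 0.8]))
        res = simulate_ensemble(prot, 1, model, fam, dt=1e-2, seed=0)
        expected = fam.force_at(0, prot.length_at(res.times))
        assert np.array_equal(res.mean_force, expected)

    def test_same_seed_is_bitwise_identical(self, make_flat_family,
                                            make_hold):
        model = _const_model([2.0, 5.0])
        fam = make_flat_family(np.linspace(20e-12, 5e-12, 7))
        prot = make_hold(0.5)
        a = simulate_ensemble(prot, 20, model, fam, dt=1e-3, seed=42)
        b = simulate_ensemble(prot, 20, model, fam, dt=1e-3, seed=42)
        assert np.array_equal(a.mean_force, b.mean_force)
        assert np.array_equal(a.final_counts, b.final_counts)
        c = simulate_ensemble(prot, 20, model, fam, dt=1e-3, seed=43)
        assert not np.array_equal(a.mean_force, c.mean_force)

    def test_survival_matches_analytic_exponential(self, make_flat_family,
                                                   make_hold):
        # single cluster, constant hazard n*u: P(no event by t) = exp(-n u t)
        n, u, t_end = 3, 0.5, 0.5
        model = _const_model([u], sizes=[n])
        fam = make_flat_family(np.full(n + 1, 5e-12))
        res = simulate_ensemble(make_hold(t_end), 2000, model, fam,
                                dt=1e-3, seed=9)
        frac_intact = np.mean(res.final_unfolded == 0)
        expected = np.exp(-n * u * t_end)
        se = np.sqrt(expected * (1 - expected) / 2000)
        assert abs(frac_intact - expected) < 4 * se

    def test_detailed_balance_reaches_binomial_occupancy(self,
                                                         make_flat_family,
                                                         make_hold):
        # u = r = 1: stationary unfolded count ~ Binomial(n, 1/2)
        n = 4
        model = _const_model([1.0], sizes=[n],
                             refolding=RefoldingParams(omega1=1.0, x_f=0.0))
        fam = make_flat_family(np.full(n + 1, 5e-12))
        res = simulate_ensemble(make_hold(8.0), 2000, model, fam,
                                dt=2e-3, seed=17)
        hist = np.bincount(res.final_unfolded, minlength=n + 1) / 2000
        from scipy.stats import binom
        tv = 0.5 * np.abs(hist - binom.pmf(np.arange(n + 1), n, 0.5)).sum()
        assert tv < 0.05

    def test_unfolded_counts_monotone_without_refolding(self, family,
                                                        default_model, ramp):
        res = simulate_ensemble(ramp, 5, default_model, family, dt=1e-3,
                                max_step_prob=1.0, seed=3,
                                retain_traces=True)
        for trace in res.traces:
            assert np.all(np.diff(trace.unfolded) >= 0)

    def test_mean_force_within_state_envelope(self, family, default_model,
                                              ramp):
        res = simulate_ensemble(ramp, 20, default_model, family, dt=1e-4,
                                seed=5)
        table = family.table(res.lengths)
        assert np.all(res.mean_force <= table.max(axis=1) + 1e-18)
        assert np.all(res.mean_force >= table.min(axis=1) - 1e-18)


class TestMce:
    def test_zero_rates_give_zero_error(self, make_flat_family, make_hold):
        model = _const_model([0.0])
        fam = make_flat_family(np.array([9e-12, 5e-12, 2e-12, 1e-12]))
        assert mce(5, 5, make_hold(0.2), model, fam, dt=1e-2, seed=0) == 0.0

    def test_quadrupling_strands_halves_the_error(self, make_flat_family,
                                                  make_hold):
        model = _const_model([2.0], sizes=[5])
        fam = make_flat_family(np.linspace(20e-12, 4e-12, 6))
        prot = make_hold(0.4)
        e1 = mce(20, 100, prot, model, fam, dt=1e-3, seed=1)
        e4 = mce(80, 100, prot, model, fam, dt=1e-3, seed=2)
        assert 0.35 < e4 / e1 < 0.65


class TestFirstUnfolding:
    def test_zero_rates_exclude_every_strand(self, make_flat_family,
                                             make_hold):
        model = _const_model([0.0])
        fam = make_flat_family(np.full(4, 5e-12))
        res = simulate_ensemble(make_hold(0.3), 30, model, fam, dt=1e-2,
                                seed=0)
        sample = first_unfolding_forces(res)
        assert sample.forces.size == 0
        assert sample.n_excluded == 30

    def test_fast_unfolding_happens_at_low_force(self, family, ramp):
        model = single_cluster_model(omega0=50.0)
        res = simulate_ensemble(ramp, 30, model, family, dt=1e-4, seed=1,
                                max_step_prob=1.0)
        sample = first_unfolding_forces(res)
        assert sample.n_excluded == 0
        # hazard 50/s per domain: events within ~ms, while force onset
        # is still near zero
        assert np.max(sample.forces) < 5e-12
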