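"""Deterministic dynamics: rate equations, closed-form steady state,
critical community sizes and sweeps."""

import numpy as np
import pytest

from communityeffect import (
    critical_size,
    derived_constants,
    integrate,
    make_default_params,
    rhs,
    steady_state,
    steady_state_limit,
    sweep,
)
from communityeffect.core import EPSILON_FAST, EPSILON_SLOW
from communityeffect.deterministic import default_initial

MIN = 60.0


def damped_loop_iteration(params, damping=0.3, max_iter=100_000, tol=1e-14):
    """Independent oracle for the active steady state: iterate the scalar
    loop map Cp -> D_n * Ap(Cp)/(Ap(Cp)+K) with under-relaxation."""
    c = derived_constants(params)
    cp = max(c.K, 1.0)
    for _ in range(max_iter):
        ap = c.P_A * cp / (cp + c.K)
        new = c.D_n * ap / (ap + c.K)
        nxt = (1 - damping) * cp + damping * new
        if abs(nxt - cp) <= tol * max(cp, 1.0):
            return nxt
        cp = nxt
    raise RuntimeError("loop iteration did not converge")


class TestRHS:
    def test_origin_is_a_fixed_point(self, slow_params):
        assert np.all(rhs(np.zeros(8), slow_params) == 0)

    def test_inducer_only_state(self, slow_params):
        """With only extracellular Bp present, the pool decays and feeds Cp."""
        p = slow_params
        y = np.zeros(8)
        y[6] = 500.0
        d = rhs(y, p)
        assert d[6] == pytest.approx(-(p.n * p.epsilon + p.delta_d) * 500)
        assert d[7] == pytest.approx(p.epsilon * 500)
        assert np.all(d[:6] == 0)

    def test_negative_state_rejected(self, slow_params):
        with pytest.raises(ValueError):
            rhs(np.full(8, -1.0), slow_params)

    def test_closed_form_is_a_fixed_point(self, slow_params):
        ss = steady_state(slow_params)
        assert ss.regime == "active"
        resid = rhs(ss.as_array(), slow_params)
        assert np.max(np.abs(resid) / np.maximum(ss.as_array(), 1e-9)) < 1e-9

    @pytest.mark.parametrize("sequester", [False, True])
    def test_steady_state_unaffected_by_sequestration(self, slow_params, sequester):
        p = slow_params.replace(sequester_activator=sequester)
        ss = steady_state(p)
        resid = rhs(ss.as_array(), p)
        assert np.max(np.abs(resid)) < 1e-9 * max(ss.Bp_out_s, 1.0)


class TestIntegrate:
    def test_subcritical_community_decays_to_quiescence(self):
        p = make_default_params(epsilon=EPSILON_SLOW, n=50)
        tr = integrate(p, 10_000 * MIN)
        assert tr["Ap"].iloc[-1] < 1e-3

    def test_supercritical_community_activates_after_a_lag(self, slow_params):
        tr = integrate(slow_params, 10_000 * MIN,
                       t_eval=[0, 500 * MIN, 10_000 * MIN])
        ss = steady_state(slow_params)
        assert tr["Ap"].iloc[-1] == pytest.approx(ss.Ap_s, rel=1e-2)
        assert tr["Ap"].iloc[1] < 0.05 * tr["Ap"].iloc[-1]  # lag then rise

    def test_steady_state_independent_of_induction_level(self, slow_params):
        """Different inducer pulses converge to the same active state, but
        stronger induction shortens the approach."""
        finals, half_times = [], []
        ap_star = steady_state(slow_params).Ap_s
        grid = np.linspace(0, 10_000 * MIN, 2001)
        for init in (5, 500, 5000):
            tr = integrate(slow_params.replace(bp_out_init=init), 10_000 * MIN,
                           t_eval=grid)
            finals.append(tr["Ap"].iloc[-1])
            half_times.append(tr.loc[tr["Ap"] >= ap_star / 2, "time"].iloc[0])
        np.testing.assert_allclose(finals, ap_star, rtol=1e-4)
        assert half_times[0] > half_times[1] > half_times[2]

    def test_invalid_duration(self, slow_params):
        with pytest.raises(ValueError):
            integrate(slow_params, -1.0)

    def test_default_initial_condition(self, slow_params):
        y0 = default_initial(slow_params)
        assert y0[6] == 500 and y0.sum() == 500


class TestSteadyState:
    def test_worked_extracellular_value(self):
        """A 50-cell community at the upshifted communication rate holds a
        few thousand extracellular molecules."""
        p = make_default_params(epsilon=1.68e-6, n=50)
        assert steady_state(p).Bp_out_s == pytest.approx(3200, rel=0.02)

    def test_quiescent_below_threshold(self):
        p = make_default_params(epsilon=EPSILON_SLOW, n=50)
        ss = steady_state(p)
        assert ss.regime == "quiescent" and ss.Ap_s == 0

    def test_oracle_equivalence_randomized(self, rng):
        """Closed form == damped loop iteration == long-time ODE for random
        feasible parameter sets (sped-up rates keep integration short)."""
        from communityeffect.core import TABLE1_RATES
        for _ in range(8):
            factors = {k: v * 100 * float(rng.uniform(0.7, 1.4))
                       for k, v in TABLE1_RATES.items()}
            p0 = make_default_params(epsilon=1e-3, n=1, **factors)
            rho = derived_constants(p0).rho
            if rho <= 1.1:
                continue
            eps = p0.delta_d / (float(rng.uniform(4, 8)) * (rho - 1))
            p = p0.replace(epsilon=eps)
            n = int(np.ceil(3 * critical_size(p).n_c))
            p = p.replace(n=n)
            ss = steady_state(p)
            assert ss.regime == "active"
            cp_oracle = damped_loop_iteration(p)
            assert ss.Cp_s == pytest.approx(cp_oracle, rel=1e-9)
            tr = integrate(p, 30_000.0)
            np.testing.assert_allclose(tr.iloc[-1][1:].to_numpy(dtype=float),
                                       ss.as_array(), rtol=1e-6)

    def test_stochastic_table_anchor(self):
        """The closed form at n=500 sits at the level the ensemble statistics
        report (about 213 molecules of Ap per cell)."""
        p = make_default_params(epsilon=EPSILON_SLOW, n=500)
        assert steady_state(p).Ap_s == pytest.approx(217, abs=1)


class TestLimits:
    @pytest.mark.parametrize("a,b,expected", [
        (2, 2, 358_000), (1, 2, 308_000), (2, 1, 172_000), (1, 1, 143_000),
    ])
    def test_infinite_community_pool_limits(self, a, b, expected):
        p = make_default_params(epsilon=EPSILON_SLOW, n=1, a=a, b=b)
        assert steady_state_limit(p).Bp_out_s == pytest.approx(expected, rel=5e-3)

    def test_limit_quiescent_when_gain_too_small(self):
        from communityeffect import FullModelParams
        p = FullModelParams(beta=0.0, n=10)
        assert steady_state_limit(p).regime == "quiescent"


class TestCriticalSize:
    @pytest.mark.parametrize("eps,a,b,expected", [
        (EPSILON_SLOW, 1, 1, 97), (EPSILON_SLOW, 2, 2, 22),
        (EPSILON_SLOW, 1, 2, 45), (1.12e-6, 1, 1, 50),
    ])
    def test_reported_thresholds(self, eps, a, b, expected):
        p = make_default_params(epsilon=eps, n=1, a=a, b=b)
        assert round(critical_size(p).n_c) == expected

    def test_infeasible_when_copy_weighted_gain_below_one(self):
        from communityeffect import FullModelParams
        p = FullModelParams(beta=1.16e-2 / 4, n=10)  # rho ~ 7.2/16 < 1
        cs = critical_size(p)
        assert not cs.feasible and np.isinf(cs.n_c) and cs.n_c_int is None

    def test_monotone_in_environment(self, rng):
        """n_c falls with faster communication and rises with faster
        extracellular decay."""
        p = make_default_params(epsilon=EPSILON_SLOW, n=1)
        eps = np.sort(10 ** rng.uniform(-7, -5, 6))
        ncs = [critical_size(p.replace(epsilon=float(e))).n_c for e in eps]
        assert np.all(np.diff(ncs) < 0)
        dds = np.sort(10 ** rng.uniform(-5, -2, 6))
        ncs = [critical_size(p.replace(delta_d=float(d))).n_c for d in dds]
        assert np.all(np.diff(ncs) > 0)

    def test_threshold_predicts_regime(self, rng):
        for _ in range(20):
            p = make_default_params(
                epsilon=float(10 ** rng.uniform(-7, -5)),
                n=int(rng.integers(1, 600)),
                a=int(rng.integers(1, 3)), b=int(rng.integers(1, 3)))
            cs = critical_size(p)
            expected = "active" if cs.feasible and p.n > cs.n_c else "quiescent"
            assert steady_state(p).regime == expected


class TestSweep:
    def test_n_sweep_flips_at_threshold(self):
        p = make_default_params(epsilon=EPSILON_SLOW, n=1)
        df = sweep(p, "n", list(range(10, 501, 1)))
        quiescent = df.loc[df["regime"] == "quiescent", "n"]
        active = df.loc[df["regime"] == "active", "n"]
        # n_c = 96.67, so 97 is the smallest integer community that activates
        assert quiescent.max() == 96 and active.min() == 97
        assert df.loc[df["first_active"], "n"].item() == 97
        assert critical_size(p).n_c_int == 97

    def test_epsilon_sweep_jumps_near_threshold(self):
        """At n ~ n_c the pool steady state is razor-sensitive to the
        communication rate."""
        p = make_default_params(epsilon=EPSILON_SLOW, n=50)
        df = sweep(p, "epsilon", [0.56e-6, 1.12e-6, 1.68e-6])
        assert df["Bp_out"].iloc[0] == 0.0
        assert 0 < df["Bp_out"].iloc[1] < 100
        assert df["Bp_out"].iloc[2] == pytest.approx(3200, rel=0.02)

    def test_monotone_growth_and_saturation(self):
        p = make_default_params(epsilon=EPSILON_SLOW, n=1)
        df = sweep(p, "n", list(range(100, 20001, 100)))
        assert np.all(np.diff(df["Ap"]) >= -1e-9)
        assert np.all(np.diff(df["Bp_out"]) >= -1e-9)
        lim = steady_state_limit(p)
        # Ap saturates quickly; Bp_out keeps climbing toward its ceiling
        assert df["Ap"].iloc[-1] == pytest.approx(lim.Ap_s, rel=0.02)
        assert df["Bp_out"].iloc[-1] < lim.Bp_out_s

    def test_expression_insensitive_to_epsilon_for_large_communities(self):
        # n must be far above n_c ~ 97 for the epsilon-independence plateau
        p = make_default_params(epsilon=EPSILON_SLOW, n=5000)
        ap1 = steady_state(p).Ap_s
        ap2 = steady_state(p.replace(epsilon=EPSILON_SLOW * 1.2)).Ap_s
        assert abs(ap2 - ap1) / ap1 < 0.02

    def test_heterozygous_never_reaches_homozygous_expression(self):
        p22 = make_default_params(epsilon=EPSILON_SLOW, n=1, a=2, b=2)
        p12 = p22.replace(a=1, b=2)
        ns = list(range(25, 2001, 25))
        ap22 = sweep(p22, "n", ns)["Ap"]
        ap12 = sweep(p12, "n", ns)["Ap"]
        assert np.all(ap12 < ap22)
        assert steady_state_limit(p12).Ap_s < steady_state_limit(p22).Ap_s

    def test_sweep_input_validation(self, slow_params):
        with pytest.raises(ValueError):
            sweep(slow_params, "kappa", [1, 2])
        with pytest.raises(ValueError):
            sweep(slow_params, "n", [])
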