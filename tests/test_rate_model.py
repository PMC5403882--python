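"""Unit and property tests of the four-population rate model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1micro import rate_model as rm


@pytest.fixture(scope="module")
def params():
    return rm.RateModelParams()


class TestGain:
    @pytest.mark.parametrize("u,expected", [
        (360.0, 0.0),        # at threshold
        (361.0, 5.33),       # unit excess drive
        (460.0, 53.3),       # sqrt(100) * 5.33
        (300.0, 0.0),        # below threshold
    ])
    def test_values(self, u, expected):
        assert rm.gain(u, 5.33, 360.0) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=1000.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonnegative(self, u):
        g1 = rm.gain(u, 5.33, 360.0)
        g2 = rm.gain(u + 1.0, 5.33, 360.0)
        assert 0.0 <= g1 <= g2

    def test_unit_slope_point(self):
        # g(theta + 1) equals the gain coefficient for any theta
        assert rm.gain(301.0, 5.33, 300.0) == pytest.approx(5.33)


class TestDerivatives:
    def test_origin_fixed_point_when_undriven(self):
        p = rm.RateModelParams(I_e=0, I_p=0, I_s=0, I_v=0)
        d = rm.rate_derivatives(rm.RateState(), p)
        assert np.allclose(d, 0.0)

    def test_sst_line(self, params):
        # SST alone, strongly driven: df_s/dt = (-f_s + 53.3) / tau_m
        p = params.with_input("s", 460.0)
        for f_s in (0.0, 10.0, 53.3):
            d = rm.rate_derivatives(rm.RateState(f_s=f_s), p)
            assert d[2] == pytest.approx((-f_s + 53.3) / p.tau_m)

    def test_sst_unit_drive_fixed_point(self, params):
        # f_s = g(361 - 360) = 5.33 is a fixed point of the SST line
        d = rm.rate_derivatives(rm.RateState(f_s=5.33), params)
        assert d[2] == pytest.approx(0.0, abs=1e-12)

    def test_sst_receives_no_self_inhibition(self, params):
        d1 = rm.rate_derivatives(rm.RateState(f_s=2.0), params)
        d2 = rm.rate_derivatives(rm.RateState(f_s=80.0), params)
        # net SST drive is independent of f_s: relaxation only
        assert d2[2] - d1[2] == pytest.approx((2.0 - 80.0) / params.tau_m)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            rm.RateModelParams(S_ee=-1.0)
        with pytest.raises(ValueError):
            rm.RateModelParams(tau_m=0.0)
        with pytest.raises(KeyError):
            rm.RateModelParams.from_dict({"S_zz": 1.0})


class TestIntegration:
    def test_undriven_stays_at_origin(self):
        p = rm.RateModelParams(I_e=0, I_p=0, I_s=0, I_v=0)
        _, traj = rm.integrate_rates(p, rm.RateState(), 100.0, 0.05)
        assert np.allclose(traj[-1], 0.0)

    def test_converges_to_only_sst_state(self, params):
        p = params.with_input("s", 460.0)
        _, traj = rm.integrate_rates(p, rm.RateState(), 500.0, 0.05)
        assert traj[-1] == pytest.approx([0.0, 0.0, 53.3, 0.0], abs=1e-6)

    def test_nonnegativity(self, params):
        rng = np.random.default_rng(3)
        for _ in range(5):
            f0 = rm.RateState.from_array(rng.uniform(0, 60, 4))
            _, traj = rm.integrate_rates(params, f0, 300.0, 0.05)
            assert np.all(traj >= 0.0)

    def test_rejects_bad_steps(self, params):
        with pytest.raises(ValueError):
            rm.integrate_rates(params, rm.RateState(), 10.0, 0.0)


class TestSteadyStates:
    def test_undriven_origin_only(self):
        p = rm.RateModelParams(I_e=0, I_p=0, I_s=0, I_v=0)
        sols = rm.enumerate_steady_states(p, seed=0)
        assert len(sols) == 1
        assert sols[0].active_set == frozenset()
        assert sols[0].stability == "stable"

    def test_only_sst_state_found(self, params):
        p = params.with_input("s", 460.0)
        sols = rm.enumerate_steady_states(p, seed=0)
        target = [s for s in sols if s.active_set == frozenset("s")]
        assert len(target) == 1
        assert target[0].state.f_s == pytest.approx(53.3, abs=1e-6)
        assert target[0].stability == "stable"

    def test_stable_states_are_attractors(self, params):
        # fixed-point/integration consistency: each stable state attracts
        # a small perturbation of itself
        sols = rm.enumerate_steady_states(params, seed=1)
        stable = [s for s in sols if s.stability == "stable"]
        assert stable, "default circuit must have a stable state"
        rng = np.random.default_rng(0)
        for s in stable:
            f0 = np.maximum(s.rates + rng.uniform(-0.05, 0.05, 4), 0.0)
            _, traj = rm.integrate_rates(
                params, rm.RateState.from_array(f0), 800.0, 0.05)
            assert np.max(np.abs(traj[-1] - s.rates)) < 1e-4

    def test_integration_limit_points_are_enumerated(self, params):
        # every limit point of integration from random starts appears in
        # the enumeration (tolerance 1e-6 Hz on the residual check)
        sols = rm.enumerate_steady_states(params, seed=1)
        rng = np.random.default_rng(7)
        for _ in range(6):
            f0 = rm.RateState.from_array(rng.uniform(0, 40, 4))
            _, traj = rm.integrate_rates(params, f0, 1500.0, 0.05)
            end = traj[-1]
            if np.max(np.abs(traj[-1] - traj[-200])) > 1e-7:
                continue  # not settled to a point (cycle)
            assert any(np.max(np.abs(end - s.rates)) < 1e-4 for s in sols)

    def test_marginal_never_guessed(self, params):
        ss = rm.enumerate_steady_states(params, seed=0)[0]
        with pytest.raises(ValueError):
            rm.classify_stability(
                params, rm.SteadyState(rm.RateState(10, 10, 10, 10),
                                       frozenset("epsv"), "unknown"))


class TestScan:
    def test_grid_must_increase(self, params):
        with pytest.raises(ValueError):
            rm.scan_input(params, "s", [1.0, 1.0])

    def test_branch_table_schema(self, params):
        scan = rm.scan_input(params, "s", [350.0, 370.0], n_starts=40,
                             detect_cycles=False)
        df = scan.to_frame()
        assert list(df.columns) == ["varied_value", "branch_id", "f_e",
                                    "f_p", "f_s", "f_v", "stability"]
        assert set(df["varied_value"]) == {350.0, 370.0}

    def test_vip_effective_threshold_shift(self, params):
        # with SST held active, the VIP activation point shifts up by
        # S_vs * f_s
        f_s = 4.0
        drive = params.theta + params.S_vs * f_s
        u_below = rm.net_drives(np.array([0, 0, f_s, 0.0]),
                                params.with_input("v", drive - 1e-9))[3]
        u_above = rm.net_drives(np.array([0, 0, f_s, 0.0]),
                                params.with_input("v", drive + 1.0))[3]
        assert rm.gain(u_below, params.gain_coeff_v, params.theta) == 0.0
        assert rm.gain(u_above, params.gain_coeff_v, params.theta) > 0.0


class TestThresholds:
    def test_vip_activation_equals_theta(self, params):
        assert rm.vip_activation_threshold(params) == 360.0
        p2 = rm.replace(params, theta=300.0)
        assert rm.vip_activation_threshold(p2) == 300.0

    def test_silencing_requires_sst_pathways(self, params):
        # SST decoupled from Pyr (directly and via PV): cannot silence
        p = rm.replace(params, S_es=0.0, S_ps=0.0)
        with pytest.raises(RuntimeError, match="not in range"):
            rm.sst_silencing_threshold(p, n_starts=40,
                                       scan_range=(350.0, 420.0))

    def test_rejects_coarse_grid(self, params):
        with pytest.raises(ValueError):
            rm.sst_silencing_threshold(params, grid_step=2.0)


class TestLimitCycleDetector:
    def test_quiet_system_has_no_cycle(self, params):
        assert rm.detect_limit_cycle(params, rm.RateState(),
                                     duration=600.0, discard=300.0) is None
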