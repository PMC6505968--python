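import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainabc.models import (
    VesselWallParams,
    muscular_tension,
    simulate,
    simulate_batch,
    steady_state,
)
from brainabc.models.minibrain import steady_cbf


class TestMuscularTension:
    def test_peak_at_optimum_radius(self):
        w = VesselWallParams(T_max=3.7, r_m=0.027, r_t=0.018, n_m=1.83)
        assert muscular_tension(0.027, w) == pytest.approx(3.7)

    def test_value_at_shape_radius_is_t_max_over_e(self):
        w = VesselWallParams(T_max=1.0, r_m=0.027, r_t=0.018, n_m=1.83)
        assert muscular_tension(0.018, w) == pytest.approx(np.exp(-1.0))

    def test_default_shape_value(self):
        # direct high-precision evaluation of exp(-|(r-r_m)/(r_t-r_m)|^n_m)
        w = VesselWallParams(T_max=1.0, r_m=0.027, r_t=0.018, n_m=1.83)
        expected = np.exp(-(abs((0.022 - 0.027) / (0.018 - 0.027)) ** 1.83))
        assert muscular_tension(0.022, w) == pytest.approx(expected, rel=1e-12)
        assert muscular_tension(0.022, w) == pytest.approx(0.711, abs=5e-4)

    @given(st.floats(0.0, 0.02, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_about_r_m(self, delta):
        w = VesselWallParams(T_max=2.0, r_m=0.027, r_t=0.018, n_m=1.83)
        assert muscular_tension(0.027 + delta, w) == pytest.approx(
            muscular_tension(0.027 - delta, w), rel=1e-12
        )

    def test_decreasing_away_from_peak(self):
        w = VesselWallParams(T_max=1.0, r_m=0.027, r_t=0.018, n_m=1.83)
        r = np.linspace(0.027, 0.06, 50)
        np.testing.assert_array_less(np.diff(muscular_tension(r, w)), 0)

    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError):
            VesselWallParams(T_max=1.0, r_m=0.02, r_t=0.02, n_m=1.83)


class TestSteadyState:
    def test_residual_below_tolerance(self, minibrain, baseline_inputs):
        y0 = steady_state(minibrain, None, baseline_inputs, tol=1e-8)
        u0 = np.array([baseline_inputs[n] for n in minibrain.input_names])
        res = np.asarray(minibrain.rhs(0.0, y0, minibrain.default_theta(), u0))
        assert np.linalg.norm(res) <= 1e-8

    def test_baseline_cbf_is_normalised_to_one(self, minibrain, baseline_inputs):
        assert steady_cbf(minibrain, None, baseline_inputs) == pytest.approx(1.0, abs=1e-6)

    def test_stiffened_vessel_lowers_cbf(self, minibrain, baseline_inputs):
        q_healthy = steady_cbf(minibrain, {"r_t": 0.018}, baseline_inputs)
        q_impaired = steady_cbf(minibrain, {"r_t": 0.013}, baseline_inputs)
        assert q_impaired < q_healthy

    def test_deterministic(self, minibrain, baseline_inputs):
        a = steady_state(minibrain, None, baseline_inputs)
        b = steady_state(minibrain, None, baseline_inputs)
        np.testing.assert_array_equal(a, b)

    def test_disabled_autoregulation_ignores_reactivities(self, minibrain, baseline_inputs):
        base = steady_state(minibrain, {"k_aut": 0.0}, baseline_inputs)
        perturbed = steady_state(
            minibrain, {"k_aut": 0.0, "R_auto": 2.9, "R_autc": 0.4}, baseline_inputs
        )
        np.testing.assert_allclose(perturbed, base, rtol=1e-12)


class TestSimulate:
    def test_constant_inputs_give_flat_outputs(self, minibrain):
        from brainabc.timeseries import TimeSeriesSet

        t = np.arange(0.0, 300.0, 1.0)
        ins = TimeSeriesSet(
            t,
            {"ABP": np.full_like(t, 100.0), "SaO2": np.full_like(t, 97.0),
             "PaCO2": np.full_like(t, 40.0)},
        )
        out = simulate(minibrain, None, ins)
        for ch in minibrain.delta_outputs:
            assert np.max(np.abs(out[ch])) <= 1e-5, ch
        assert np.ptp(out["TOI"]) <= 1e-5

    def test_hypoxia_lowers_toi(self, minibrain, healthy_protocol):
        ins, _ = healthy_protocol
        out = simulate(minibrain, None, ins)
        assert out["TOI"].min() < out["TOI"][0] - 5.0

    def test_missing_input_channel_rejected(self, minibrain, healthy_protocol):
        ins, _ = healthy_protocol
        from brainabc.timeseries import TimeSeriesSet

        broken = TimeSeriesSet(ins.t, {"ABP": ins["ABP"], "SaO2": ins["SaO2"]})
        with pytest.raises(KeyError, match="PaCO2"):
            simulate(minibrain, None, broken)

    def test_batch_path_matches_adaptive_integrator(self, minibrain, healthy_protocol):
        ins, _ = healthy_protocol
        for rt in (0.018, 0.013):
            ref = simulate(minibrain, {"r_t": rt}, ins)
            bat = simulate_batch(minibrain, {"r_t": np.array([rt])}, ins)
            for ch in ("TOI", "DHbO2", "DHHb", "DCCO"):
                scale = max(np.ptp(ref[ch]), 1e-9)
                assert np.max(np.abs(bat[ch][0] - ref[ch])) / scale < 1e-2, (rt, ch)


class TestAutoregulationShape:
    def test_pressure_response_sign_flips_with_stiffening(self, minibrain):
        """At high pressure, flow rises with ABP for the normal vessel but
        falls for the stiffened one (autoregulation overcompensates)."""
        def dq_dabp(rt):
            lo = steady_cbf(minibrain, {"r_t": rt}, {"ABP": 128.0, "SaO2": 97.0, "PaCO2": 40.0})
            hi = steady_cbf(minibrain, {"r_t": rt}, {"ABP": 132.0, "SaO2": 97.0, "PaCO2": 40.0})
            return (hi - lo) / 4.0

        assert dq_dabp(0.018) >= 0.0
        assert dq_dabp(0.013) <= 0.0

    @pytest.mark.parametrize("sao2", [70.0, 80.0, 90.0, 97.0])
    def test_stiffened_cbf_lower_across_saturations(self, minibrain, sao2):
        ins = {"ABP": 100.0, "SaO2": sao2, "PaCO2": 40.0}
        assert steady_cbf(minibrain, {"r_t": 0.013}, ins) < steady_cbf(
            minibrain, {"r_t": 0.018}, ins
        )

    def test_impaired_responses_smaller_in_every_delta_output(
        self, minibrain, healthy_protocol, impaired_protocol
    ):
        _, healthy = healthy_protocol
        _, impaired = impaired_protocol
        for ch in minibrain.delta_outputs:
            assert np.ptp(impaired[ch]) < np.ptp(healthy[ch]), ch


class TestAlgebraicStates:
    def test_mixed_dae_solved_by_nested_root_finds(self):
        """A 2-state DAE (dy/dt = -y + z, 0 = z - u(t)) must track its
        algebraic constraint exactly and integrate the differential state."""
        from brainabc.models.core import ModelDefinition, ParameterSpec
        from brainabc.timeseries import TimeSeriesSet

        def rhs(t, y, theta, u):
            return np.array([-y[0] + y[1], y[1] - u[0]])

        model = ModelDefinition(
            name="dae-demo",
            state_names=["y", "z"],
            differential_flags=[True, False],
            rhs=rhs,
            input_names=["u"],
            output_names=["y", "z"],
            outputs=lambda t, Y, theta, U: {"y": Y[0], "z": Y[1]},
            parameter_table={"dummy": ParameterSpec("dummy", 1.0)},
            initial_guess=lambda theta, u0: np.array([u0[0], u0[0]]),
        )
        t = np.arange(0.0, 40.0, 1.0)
        u = np.where(t < 5, 1.0, 2.0)
        ins = TimeSeriesSet(t, {"u": u})
        out = simulate(model, None, ins, rtol=1e-8, atol=1e-11)
        np.testing.assert_allclose(out["z"], u, atol=1e-6)
        # after the step the differential state relaxes to 2 with tau = 1 s
        assert out["y"][-1] == pytest.approx(2.0, abs=1e-4)
        assert out["y"][0] == pytest.approx(1.0)
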