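"""Pre-setting search, PID primitive, motion laws, interlock, closed loop."""

import numpy as np
import pytest

from graftsim.circuit import CircuitModel, NoiseSpec, ValveLaw, steady_state_sensor_pressure
from graftsim.control import (
    ISO_REGIMES,
    MotionLaw,
    PIDGains,
    PIDMemory,
    PressureRegime,
    SafetyLimits,
    motion_profile,
    pid_step,
    preset_occlusions,
    run_regulated_stimulation,
    safety_check,
)
from graftsim.errors import ConfigurationError


class TestPresetOcclusions:
    def test_normotensive_converges_within_tolerance(self, ct_model):
        regime = PressureRegime(80.0, 120.0)
        res = preset_occlusions(ct_model, regime)
        assert res.converged
        assert res.closure_at_pmin < res.closure_at_pmax
        for closure, target in (
            (res.closure_at_pmin, 80.0),
            (res.closure_at_pmax, 120.0),
        ):
            p = steady_state_sensor_pressure(ct_model, closure)
            assert abs(p - target) <= regime.tolerance

    def test_invalid_regime_rejected(self):
        with pytest.raises(ConfigurationError):
            PressureRegime(120.0, 80.0)

    def test_unreachable_target_reports_nonconvergence(self):
        # fully closed valve cannot reach an absurd pressure target
        model = CircuitModel.compliance_test(
            pump_flow=10.0,
            valve_law=ValveLaw(open_resistance=0.01, occluded_resistance=100.0),
        )
        res = preset_occlusions(model, PressureRegime(80.0, 5000.0))
        assert not res.converged
        assert "unreachable" in res.diagnostic

    def test_target_below_open_pressure_reports_nonconvergence(self):
        model = CircuitModel.compliance_test(pump_flow=500.0, sample_resistance=0.5)
        res = preset_occlusions(model, PressureRegime(5.0, 120.0))
        assert not res.converged

    def test_randomized_circuits_hit_targets(self):
        # pre-setting correctness over randomized reachable parameterizations
        rng = np.random.default_rng(42)
        for _ in range(20):
            model = CircuitModel.compliance_test(
                pump_flow=float(rng.uniform(150.0, 400.0)),
                filter_compliance=float(rng.uniform(0.005, 0.05)),
                segment_resistances=(
                    float(rng.uniform(0.01, 0.1)),
                    float(rng.uniform(0.005, 0.05)),
                ),
                sample_resistance=float(rng.uniform(0.02, 0.1)),
                valve_law=ValveLaw(
                    open_resistance=float(open_r := rng.uniform(0.02, 0.08)),
                    occluded_resistance=float(open_r * rng.uniform(1.0e4, 3.0e4)),
                ),
            )
            regime = PressureRegime(80.0, 120.0)
            assert steady_state_sensor_pressure(model, 0.0) < 78.0
            res = preset_occlusions(model, regime)
            assert res.converged
            for closure, target in (
                (res.closure_at_pmin, 80.0),
                (res.closure_at_pmax, 120.0),
            ):
                p = steady_state_sensor_pressure(model, closure)
                assert abs(p - target) <= regime.tolerance


class TestPIDStep:
    def test_zero_error_zero_memory_gives_zero(self):
        out, _ = pid_step(0.0, 1.0, PIDGains(), PIDMemory())
        assert out == 0.0

    def test_proportional_only_limit(self):
        gains = PIDGains(kp=0.002, ki=0.0, kd=0.0)
        mem = PIDMemory()
        for _ in range(5):
            out, mem = pid_step(3.0, 1.0, gains, mem)
            assert out == pytest.approx(0.002 * 3.0)

    def test_step_response_matches_hand_unrolled_recursion(self):
        gains = PIDGains(
            kp=0.01, ki=0.002, kd=0.005, output_min=0.0, output_max=1.0,
            anti_windup_limit=50.0,
        )
        errors = [4.0, 3.0, 2.5, 2.0, 1.0, 0.5, 0.0, -0.5, -1.0, -0.25]
        dt = 1.0
        # independent hand-unrolled discrete PID with integral clamp
        integral, prev, first = 0.0, 0.0, True
        expected = []
        for e in errors:
            integral = min(max(integral + e * dt, -50.0), 50.0)
            deriv = 0.0 if first else (e - prev) / dt
            raw = gains.kp * e + gains.ki * integral + gains.kd * deriv
            expected.append(min(max(raw, 0.0), 1.0))
            prev, first = e, False
        mem = PIDMemory()
        got = []
        for e in errors:
            out, mem = pid_step(e, dt, gains, mem)
            got.append(out)
        assert got == pytest.approx(expected, abs=1e-15)

    def test_output_clamped(self):
        gains = PIDGains(kp=1.0, ki=0.0, output_min=0.1, output_max=0.9)
        out, _ = pid_step(100.0, 1.0, gains, PIDMemory())
        assert out == 0.9
        out, _ = pid_step(-100.0, 1.0, gains, PIDMemory())
        assert out == 0.1

    def test_integral_anti_windup(self):
        gains = PIDGains(kp=0.0, ki=1.0, anti_windup_limit=2.0, output_max=1.0)
        mem = PIDMemory()
        for _ in range(10):
            _, mem = pid_step(5.0, 1.0, gains, mem)
        assert mem.integral == 2.0


class TestMotionProfile:
    def test_coronary_apex_at_half_systole(self):
        law = MotionLaw(kind="coronary_piecewise", baseline_closure=0.1, peak_closure=0.4)
        assert motion_profile(0.175, law) == pytest.approx(0.4)

    def test_coronary_diastole_at_minimal_compression(self):
        law = MotionLaw(kind="coronary_piecewise", baseline_closure=0.1, peak_closure=0.4)
        assert motion_profile(0.5, law) == 0.1
        assert motion_profile(0.99, law) == 0.1

    def test_sinusoidal_periodicity(self):
        law = MotionLaw(kind="sinusoidal", baseline_closure=0.2, peak_closure=0.3)
        for t in (0.0, 0.13, 0.77):
            assert motion_profile(t, law) == pytest.approx(
                motion_profile(t + law.period, law)
            )

    def test_sinusoidal_oscillates_between_baseline_and_peak(self):
        law = MotionLaw(kind="sinusoidal", baseline_closure=0.2, peak_closure=0.5)
        t = np.linspace(0, 1, 101)
        c = np.array([motion_profile(tt, law) for tt in t])
        assert c.min() == pytest.approx(0.2)
        assert c.max() == pytest.approx(0.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            MotionLaw(kind="triangular")

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            motion_profile(-0.1, MotionLaw())


class TestSafety:
    def test_within_limits_continues(self):
        assert safety_check(100.0, SafetyLimits(pressure_max=200.0, pressure_min=0.001))

    def test_breach_aborts(self):
        assert not safety_check(250.0, SafetyLimits(pressure_max=200.0, pressure_min=0.001))

    def test_run_aborts_and_truncates_on_breach(self, ct_model):
        regime = PressureRegime(80.0, 120.0)
        res = run_regulated_stimulation(
            ct_model, regime, "sinusoidal", n_cycles=10, seed=3,
            safety=SafetyLimits(pressure_max=100.0, pressure_min=5.0),
        )
        assert res.aborted
        assert res.abort_time is not None
        assert res.abort_pressure > 100.0
        assert res.pressure.duration < 10.0  # truncated before the full run


class TestRegulatedStimulation:
    def test_normotensive_extremes_track_targets(self, ct_run):
        log = ct_run.controller_log
        post = log.iloc[ct_run.settle_cycles:]
        assert post.p_min_meas.mean() == pytest.approx(80.0, abs=1.0)
        assert post.p_max_meas.mean() == pytest.approx(120.0, abs=1.0)

    def test_extremes_within_tolerance_after_settling(self, ct_run, coronary_run):
        for run in (ct_run, coronary_run):
            post = run.controller_log.iloc[run.settle_cycles:]
            assert (post.p_min_meas - 80.0).abs().max() <= run.regime.tolerance + 0.5
            assert (post.p_max_meas - 120.0).abs().max() <= run.regime.tolerance + 0.5

    @pytest.mark.parametrize("name", list(ISO_REGIMES))
    def test_all_iso_regimes_tracked(self, ct_model, name):
        lo, hi = ISO_REGIMES[name]
        res = run_regulated_stimulation(
            ct_model, PressureRegime(lo, hi), "sinusoidal", n_cycles=20, seed=2
        )
        post = res.controller_log.iloc[res.settle_cycles:]
        assert post.p_min_meas.mean() == pytest.approx(lo, abs=1.0)
        assert post.p_max_meas.mean() == pytest.approx(hi, abs=1.0)

    def test_noise_free_settling_is_monotone_towards_targets(self, ct_model):
        res = run_regulated_stimulation(
            ct_model, PressureRegime(80.0, 120.0), "sinusoidal",
            n_cycles=8, seed=0, noise=NoiseSpec(0.0, 0.0),
        )
        log = res.controller_log
        err_max = (log.p_max_meas - 120.0).abs().to_numpy()
        # settling: errors shrink from the first to the settled cycles
        assert err_max[3:].max() < err_max[0]

    def test_zero_gains_hold_open_loop_preset(self, ct_model):
        gains = PIDGains(kp=0.0, ki=0.0, kd=0.0)
        res = run_regulated_stimulation(
            ct_model, PressureRegime(80.0, 120.0), "sinusoidal",
            n_cycles=6, seed=0, gains=gains, noise=NoiseSpec(0.0, 0.0),
        )
        log = res.controller_log
        assert (log.c_min_cmd == res.preset.closure_at_pmin).all()
        assert (log.c_max_cmd == res.preset.closure_at_pmax).all()

    def test_commanded_closure_stays_in_unit_interval(self, ct_run, coronary_run):
        for run in (ct_run, coronary_run):
            log = run.controller_log
            assert ((log.c_min_cmd >= 0.0) & (log.c_min_cmd <= 1.0)).all()
            assert ((log.c_max_cmd >= 0.0) & (log.c_max_cmd <= 1.0)).all()

    def test_identical_seeds_bitwise_identical_traces(self, ct_model):
        regime = PressureRegime(80.0, 120.0)
        a = run_regulated_stimulation(ct_model, regime, "sinusoidal", n_cycles=8, seed=11)
        b = run_regulated_stimulation(ct_model, regime, "sinusoidal", n_cycles=8, seed=11)
        assert np.array_equal(a.pressure.samples, b.pressure.samples)
        assert np.array_equal(a.flow.samples, b.flow.samples)
        assert a.controller_log.equals(b.controller_log)
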