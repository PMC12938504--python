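"""Two-stage pinch-valve pressure control and the prescribed motion laws.

The control algorithm mirrors the platform firmware's workflow:

1. **Pre-setting phase** -- with the pump running, the valve closure is
   ramped gradually from fully open; the steady sensor pressure is
   compared against the user-defined targets, and the closure levels that
   produce Pmin and then Pmax (within the regime tolerance) are recorded.
   The twin refines the ramp hit with bisection, which is exact here
   because the steady closure->pressure map is strictly increasing.
2. **Regulated stimulation phase** -- the valve follows a periodic motion
   law scaled between the two pre-set closure levels.  Because the
   hydraulic network is dynamic, the pressure extremes actually reached
   during cycling differ from the steady-state values, so a discrete PID
   loop corrects the closure envelope once per cycle from the measured
   per-cycle pressure extremes (the controller is pressure-referenced and
   regulates exactly the quantities the bench reports: per-cycle Pmin and
   Pmax on the filtered 40 Hz sensor stream).

Two motion laws are provided: a full sinusoid (compliance testing at
1 Hz) and the coronary piecewise law -- a half-period sinusoidal closure
over the 0.35 s systolic phase followed by a 0.65 s diastolic phase at
minimal compression.  A safety interlock aborts any run whose sensor
pressure leaves the configured window; on abort the twin zeroes the pump
and opens the valve, and the returned traces are truncated and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import (
    CircuitModel,
    NoiseSpec,
    _flows,
    _pump_flow_at,
    steady_state_sensor_pressure,
)
from .errors import ConfigurationError, ControllerError
from .waveforms import SignalTrace, moving_average_3

__all__ = [
    "PressureRegime",
    "ISO_REGIMES",
    "PresetResult",
    "PIDGains",
    "PIDMemory",
    "MotionLaw",
    "SafetyLimits",
    "preset_occlusions",
    "pid_step",
    "motion_profile",
    "safety_check",
    "run_regulated_stimulation",
    "StimulationResult",
]


@dataclass(frozen=True)
class PressureRegime:
    """Target pulsatile pressure regime (two levels at a frequency)."""

    p_min_target: float  # mmHg
    p_max_target: float  # mmHg
    frequency: float = 1.0  # Hz
    tolerance: float = 2.0  # mmHg

    def __post_init__(self) -> None:
        if self.p_min_target >= self.p_max_target:
            raise ConfigurationError("p_min_target must be < p_max_target")
        if self.frequency <= 0:
            raise ConfigurationError("frequency must be > 0")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


#: The three ISO 7198 pulsatile regimes (mmHg), all at 1 Hz.
ISO_REGIMES = {
    "hypotension": (50.0, 90.0),
    "normotension": (80.0, 120.0),
    "hypertension": (110.0, 150.0),
}


@dataclass(frozen=True)
class PresetResult:
    """Outcome of the pre-setting search."""

    closure_at_pmin: float
    closure_at_pmax: float
    iterations: int
    converged: bool
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if self.converged and not self.closure_at_pmin < self.closure_at_pmax:
            raise ConfigurationError(
                "converged preset requires closure_at_pmin < closure_at_pmax"
            )


def preset_occlusions(
    model: CircuitModel,
    regime: PressureRegime,
    step: float = 0.002,
    max_iter: int = 2000,
) -> PresetResult:
    """Search the valve closure levels that reach Pmin and then Pmax.

    Ramps the closure upward from fully open in increments of ``step``,
    evaluating the steady-state sensor pressure at each level; the first
    level whose pressure crosses a target brackets it, and bisection
    refines the bracket until the steady pressure is within the regime
    tolerance of the target (refined further to tolerance/10 to give the
    PID a tight starting envelope).  Pmin is located first, then the ramp
    continues upward for Pmax.

    Non-convergence (target below the fully-open pressure, above the
    fully-closed pressure, or ``max_iter`` exhausted) returns a
    ``PresetResult`` with ``converged=False`` and a diagnostic.
    """
    iterations = 0
    closures = []
    c = 0.0

    def pressure_at(closure: float) -> float:
        return steady_state_sensor_pressure(model, closure)

    for target in (regime.p_min_target, regime.p_max_target):
        if pressure_at(c) > target + regime.tolerance and not closures:
            return PresetResult(
                0.0, 0.0, iterations, False,
                diagnostic=f"target {target} mmHg below fully-open pressure",
            )
        lo, hi = None, None
        while c <= 1.0:
            iterations += 1
            if iterations > max_iter:
                return PresetResult(
                    0.0, 0.0, iterations, False, diagnostic="max_iter exhausted"
                )
            if pressure_at(c) >= target:
                hi = c
                lo = max(c - step, 0.0)
                break
            c += step
        if hi is None:
            return PresetResult(
                0.0, 0.0, iterations, False,
                diagnostic=f"target {target} mmHg unreachable at full closure",
            )
        # bisection refinement inside the bracketing ramp step
        refine = regime.tolerance / 10.0
        while abs(pressure_at((lo + hi) / 2.0) - target) > refine:
            iterations += 1
            if iterations > max_iter:
                break
            mid = (lo + hi) / 2.0
            if pressure_at(mid) < target:
                lo = mid
            else:
                hi = mid
        closures.append((lo + hi) / 2.0)
        c = hi  # continue the ramp upward for the next target

    c_pmin, c_pmax = closures
    for cc, target in zip(closures, (regime.p_min_target, regime.p_max_target)):
        if abs(pressure_at(cc) - target) > regime.tolerance:
            return PresetResult(
                0.0, 0.0, iterations, False,
                diagnostic=f"steady pressure at closure {cc:.4f} misses {target} mmHg",
            )
    return PresetResult(c_pmin, c_pmax, iterations, True)


@dataclass(frozen=True)
class PIDGains:
    """Discrete PID gains in closure fraction per mmHg.

    ``output_min``/``output_max`` clamp the commanded closure (the PID
    output including its feedforward bias) and must lie within [0, 1].
    The integral accumulator is clamped to +-``anti_windup_limit``
    (mmHg * cycle).
    """

    kp: float = 8.0e-4
    ki: float = 1.8e-3
    kd: float = 0.0
    output_min: float = 0.0
    output_max: float = 1.0
    anti_windup_limit: float = 300.0
    max_step: float = 0.05  # closure slew limit per correction
    error_filter_alpha: float = 0.7  # EMA weight on per-cycle error (1 = off)

    def __post_init__(self) -> None:
        if not 0.0 <= self.output_min < self.output_max <= 1.0:
            raise ConfigurationError("require 0 <= output_min < output_max <= 1")
        if self.anti_windup_limit <= 0:
            raise ConfigurationError("anti_windup_limit must be > 0")
        if self.max_step <= 0:
            raise ConfigurationError("max_step must be > 0")
        if not 0.0 < self.error_filter_alpha <= 1.0:
            raise ConfigurationError("error_filter_alpha must be in (0, 1]")


@dataclass(frozen=True)
class PIDMemory:
    """Controller memory carried between PID steps."""

    integral: float = 0.0
    prev_error: float = 0.0
    initialized: bool = False


def pid_step(
    error: float,
    dt: float,
    gains: PIDGains,
    memory: PIDMemory,
    bias: float = 0.0,
) -> tuple[float, PIDMemory]:
    """One discrete PID update; returns (output, updated memory).

    ``output = clamp(bias + kp*e + ki*I + kd*de/dt, output_min, output_max)``
    with the integral ``I`` clamped to the anti-windup limit.  ``bias`` is
    the feedforward operating point (the pre-set closure in the regulated
    stimulation loop); with ``bias = 0`` the output is the raw, clamped
    PID adjustment.  Total function: never raises after validation of dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    integral = memory.integral + error * dt
    integral = min(max(integral, -gains.anti_windup_limit), gains.anti_windup_limit)
    deriv = 0.0 if not memory.initialized else (error - memory.prev_error) / dt
    raw = bias + gains.kp * error + gains.ki * integral + gains.kd * deriv
    out = min(max(raw, gains.output_min), gains.output_max)
    return out, PIDMemory(integral=integral, prev_error=error, initialized=True)


@dataclass(frozen=True)
class MotionLaw:
    """Periodic pinch-valve closure profile.

    Kinds:

    * ``sinusoidal`` -- full sinusoid from ``baseline_closure`` (at t=0,
      the pressure minimum) up to ``peak_closure`` and back each period.
    * ``coronary_piecewise`` -- half-sine bump from baseline to peak over
      ``systole_duration`` seconds at the start of the cycle, then
      constant baseline (minimal compression) for the diastolic
      remainder.
    * ``constant`` -- baseline closure throughout.
    """

    kind: str = "sinusoidal"
    period: float = 1.0  # s
    systole_duration: float = 0.35  # s, coronary only
    baseline_closure: float = 0.0
    peak_closure: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoidal", "coronary_piecewise", "constant"):
            raise ConfigurationError(f"unknown motion-law kind {self.kind!r}")
        if not 0.0 <= self.baseline_closure <= self.peak_closure <= 1.0:
            raise ConfigurationError(
                "require 0 <= baseline_closure <= peak_closure <= 1"
            )
        if self.period <= 0:
            raise ConfigurationError("period must be > 0")
        if self.kind == "coronary_piecewise" and not (
            0 < self.systole_duration < self.period
        ):
            raise ConfigurationError("systole_duration must be in (0, period)")


def motion_profile(t: float, law: MotionLaw) -> float:
    """Commanded closure fraction at time ``t`` (s) under a motion law."""
    if t < 0:
        raise ValueError("t must be >= 0")
    amp = law.peak_closure - law.baseline_closure
    tm = t % law.period
    if law.kind == "constant":
        return law.baseline_closure
    if law.kind == "sinusoidal":
        return law.baseline_closure + amp * 0.5 * (
            1.0 - math.cos(2.0 * math.pi * tm / law.period)
        )
    if law.kind == "coronary_piecewise":
        if tm < law.systole_duration:
            return law.baseline_closure + amp * math.sin(
                math.pi * tm / law.systole_duration
            )
        return law.baseline_closure
    raise ConfigurationError(f"unknown motion-law kind {law.kind!r}")


@dataclass(frozen=True)
class SafetyLimits:
    """Hard pressure window enforced by the interlock."""

    pressure_max: float = 250.0  # mmHg
    pressure_min: float = 5.0  # mmHg

    def __post_init__(self) -> None:
        if self.pressure_min >= self.pressure_max:
            raise ConfigurationError("pressure_min must be < pressure_max")


def safety_check(pressure: float, limits: SafetyLimits) -> bool:
    """True to continue, False to abort (pressure outside the safe window)."""
    return limits.pressure_min <= pressure <= limits.pressure_max


#: Pressure span (mmHg) at which the nominal PID gains apply; the loop
#: rescales gains to the regime's span above the valve-open baseline.
GAIN_REFERENCE_SPAN = 100.0


def _scheduled_gains(gains: PIDGains, target: float, p_open: float) -> PIDGains:
    """Static gain scheduling against the exponential valve law.

    With a log-linear valve law the steady sensor-pressure sensitivity to
    closure is proportional to the pressure excess over the valve-open
    baseline, dP/dc ~ ln(R_occ/R_open) * (P - P_open).  Scaling the gains
    by ``GAIN_REFERENCE_SPAN / (target - P_open)`` keeps the per-cycle
    loop gain level across regimes and operating points.  ``p_open`` is
    the steady sensor pressure at closure 0, which the physical
    controller observes at the start of its pre-setting ramp.
    """
    span = max(target - p_open, 1.0)
    scale = GAIN_REFERENCE_SPAN / span
    return replace(gains, kp=gains.kp * scale, ki=gains.ki * scale, kd=gains.kd * scale)


def _pid_correct(
    error: float,
    gains: PIDGains,
    memory: PIDMemory,
    bias: float,
    previous: float,
) -> tuple[float, PIDMemory]:
    """One slew-limited per-cycle envelope correction.

    Runs :func:`pid_step` around the pre-set bias and clamps the change of
    the commanded closure to ``gains.max_step`` per cycle; while the slew
    limit is active the integral is held (conditional integration), which
    keeps the loop stable in the steep upper range of the valve law.
    """
    candidate, new_memory = pid_step(error, 1.0, gains, memory, bias=bias)
    if candidate > previous + gains.max_step:
        return previous + gains.max_step, replace(memory, prev_error=error, initialized=True)
    if candidate < previous - gains.max_step:
        return previous - gains.max_step, replace(memory, prev_error=error, initialized=True)
    return candidate, new_memory


@dataclass
class StimulationResult:
    """Output of a closed-loop regulated stimulation run.

    ``pressure`` and ``flow`` are the acquired (noisy, unfiltered) sensor
    streams at 40 Hz and 200 Hz; ``pressure_highres`` is the noise-free
    sensor pressure at the simulator resolution (used to drive the
    phantom's quasi-static distension).  ``controller_log`` has one row
    per cycle: measured extremes and commanded envelope closures.
    """

    pressure: SignalTrace
    flow: SignalTrace
    pressure_highres: SignalTrace
    controller_log: pd.DataFrame
    preset: PresetResult
    regime: PressureRegime
    law_kind: str
    settle_cycles: int
    aborted: bool = False
    abort_time: float | None = None
    abort_pressure: float | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.controller_log)


def run_regulated_stimulation(
    model: CircuitModel,
    regime: PressureRegime,
    law_kind: str = "sinusoidal",
    gains: PIDGains | None = None,
    n_cycles: int = 35,
    seed: int | None = 0,
    dt: float = 1.0e-3,
    settle_cycles: int = 5,
    noise: NoiseSpec | None = None,
    safety: SafetyLimits | None = None,
    systole_duration: float = 0.35,
    pressure_rate: float = 40.0,
    flow_rate: float = 200.0,
    preset: PresetResult | None = None,
) -> StimulationResult:
    """Pre-setting followed by PID-regulated periodic valve motion.

    The motion law oscillates between two commanded closure levels,
    initialised at the pre-set values; after every cycle two PID loops
    (one per envelope edge) update the commands from that cycle's
    measured Pmin/Pmax on the filtered sensor stream.  With the default
    gains the per-cycle extremes settle to within the regime tolerance of
    the targets in at most ``settle_cycles`` (default 5) cycles.

    Sensor noise defaults to the bench model (SD 0.5 mmHg / 1 mL/min);
    pass ``NoiseSpec(0, 0)`` for a noise-free run.  The safety interlock
    checks every acquired pressure sample; on a breach the pump is zeroed,
    the valve opened, and the truncated traces returned with
    ``aborted=True``.
    """
    if noise is None:
        noise = NoiseSpec()
    if gains is None:
        gains = PIDGains()
    if safety is None:
        safety = SafetyLimits()
    if preset is None:
        preset = preset_occlusions(model, regime)
    if not preset.converged:
        raise ControllerError(f"pre-setting did not converge: {preset.diagnostic}")

    period = regime.period
    steps_per_cycle = int(round(period / dt))
    p_stride = int(round((1.0 / pressure_rate) / dt))
    q_stride = int(round((1.0 / flow_rate) / dt))
    if p_stride < 1 or q_stride < 1:
        raise ValueError("acquisition rates exceed simulator resolution")

    rng = np.random.default_rng(seed)
    comps = np.asarray(model.node_compliances)

    # schedule both envelope edges by the regime's upper span: the valve
    # law's sensitivity grows with pressure level, while the lower edge is
    # tracked more stiffly by the plant and tolerates less loop gain
    p_open = steady_state_sensor_pressure(model, 0.0)
    gains_min = _scheduled_gains(gains, regime.p_max_target, p_open)
    gains_max = gains_min

    c_min_cmd = preset.closure_at_pmin
    c_max_cmd = preset.closure_at_pmax
    mem_min = PIDMemory()
    mem_max = PIDMemory()
    ef_min: float | None = None  # EMA-filtered per-cycle errors
    ef_max: float | None = None

    # start from the equilibrium of the mid-envelope closure to limit the
    # initial transient
    from .circuit import steady_state_pressures

    pressures = steady_state_pressures(model, (c_min_cmd + c_max_cmd) / 2.0).copy()

    p_sens_all: list[float] = []
    q_sens_all: list[float] = []
    p_hi_all: list[float] = []
    log_rows = []
    aborted = False
    abort_time = None
    abort_pressure = None

    t = 0.0
    for cycle in range(n_cycles):
        law = MotionLaw(
            kind=law_kind,
            period=period,
            systole_duration=systole_duration,
            baseline_closure=min(max(c_min_cmd, 0.0), 1.0),
            peak_closure=min(max(c_max_cmd, 0.0), 1.0),
        )
        cycle_p: list[float] = []
        for i in range(steps_per_cycle):
            tm = i * dt
            c = motion_profile(tm, law)
            q_pump = _pump_flow_at(model, t)
            q_feed, q_chain, sensor, branch = _flows(model, pressures, c, q_pump)
            p_hi_all.append(sensor)
            if i % p_stride == 0:
                p_meas = sensor + rng.normal(0.0, noise.pressure_sd) if noise.pressure_sd > 0 else sensor
                p_sens_all.append(p_meas)
                cycle_p.append(p_meas)
                if not safety_check(p_meas, safety):
                    aborted = True
                    abort_time = t
                    abort_pressure = p_meas
                    break
            if i % q_stride == 0:
                q_meas = branch + rng.normal(0.0, noise.flow_sd) if noise.flow_sd > 0 else branch
                q_sens_all.append(q_meas)
            if model.service_compliance is not None:
                pressures[0] += (q_pump - q_feed) / comps[0] / 60.0 * dt
                pressures[1] += (q_feed - q_chain) / comps[1] / 60.0 * dt
            else:
                pressures[0] += (q_pump - q_chain) / comps[0] / 60.0 * dt
            t += dt
        if aborted:
            break

        # per-cycle envelope correction on the filtered sensor samples
        cp = np.asarray(cycle_p)
        if len(cp) >= 3:
            filt = np.convolve(cp, np.ones(3) / 3.0, mode="same")
            filt[0] = (cp[0] + cp[1]) / 2.0
            filt[-1] = (cp[-2] + cp[-1]) / 2.0
        else:
            filt = cp
        p_min_meas = float(filt.min())
        p_max_meas = float(filt.max())
        log_rows.append(
            {
                "cycle": cycle,
                "p_min_meas": p_min_meas,
                "p_max_meas": p_max_meas,
                "c_min_cmd": c_min_cmd,
                "c_max_cmd": c_max_cmd,
            }
        )
        # positive error (measured below target) must increase closure;
        # a per-cycle slew limit keeps the loop out of the steep end of the
        # valve law, with conditional integration while clamped
        e_min = regime.p_min_target - p_min_meas
        e_max = regime.p_max_target - p_max_meas
        a = gains.error_filter_alpha
        ef_min = e_min if ef_min is None else a * e_min + (1 - a) * ef_min
        ef_max = e_max if ef_max is None else a * e_max + (1 - a) * ef_max
        c_min_cmd, mem_min = _pid_correct(
            ef_min, gains_min, mem_min, preset.closure_at_pmin, c_min_cmd,
        )
        c_max_cmd, mem_max = _pid_correct(
            ef_max, gains_max, mem_max, preset.closure_at_pmax, c_max_cmd,
        )
        if c_min_cmd >= c_max_cmd:
            c_min_cmd = max(0.0, c_max_cmd - 1e-4)

    fs_sim = 1.0 / dt
    pressure = SignalTrace(
        np.asarray(p_sens_all), pressure_rate, kind="pressure", units="mmHg"
    )
    flow = SignalTrace(np.asarray(q_sens_all), flow_rate, kind="flow", units="mL/min")
    p_hi = SignalTrace(np.asarray(p_hi_all), fs_sim, kind="pressure", units="mmHg")
    return StimulationResult(
        pressure=pressure,
        flow=flow,
        pressure_highres=p_hi,
        controller_log=pd.DataFrame(log_rows),
        preset=preset,
        regime=regime,
        law_kind=law_kind,
        settle_cycles=settle_cycles,
        aborted=aborted,
        abort_time=abort_time,
        abort_pressure=abort_pressure,
    )
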