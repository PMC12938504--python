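"""Lumped-parameter simulation of the platform's hydraulic circuits.

Two configurations are modelled, mirroring the two bench setups:

* **compliance test** -- one roller pump feeds a pulsatility-damping
  reservoir/filter stage, then a single tubular sample, then the
  proportional pinch-valve, and returns to the vented reservoir.  The
  pressure sensor sits at the sample inlet.
* **coronary-like** -- the pump feeds the damping stage, then a service
  compliance chamber (C_s) upstream of three samples perfused in
  parallel, then the pinch-valve.  Cyclic valve closure raises circuit
  resistance so pressure rises while flow falls (volume is stored in
  C_s); on valve release the stored volume discharges through the
  samples, producing the counter-phase, diastolic-dominant flow pattern
  of the coronary circulation.

The network is a series chain: pump (flow source) -> filter node
(compliance C_f) -> feed resistance -> [service node (C_s), coronary
only] -> sample stage (n parallel equal branches) -> return resistance +
valve resistance -> vented reservoir at the outflow reference pressure.
Node pressures obey conservation, compliance * dP/dt = inflow - outflow.
Integration is fixed-step explicit Euler; with the default element values
the fastest network time constant is ~2 s, far above the 1 ms default
step, and Euler's flow bookkeeping conserves volume to round-off.

Units are fixed throughout: mmHg, mL/min, s.  Hydraulic resistance is
mmHg*min/mL and compliance mL/mmHg, so R*C is in minutes; the factor of
60 in the rate equations converts to mmHg/s.

The element values (tubing resistances, compliance volumes, valve
transfer function) are not bench measurements; they are this package's
calibration choices, sized so that all three ISO 7198 pressure regimes
are reachable within the valve's closure range and so that 180 mL/min
through a sample branch produces a physiological (~9 mmHg) pressure
drop.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ConfigurationError, SimulationError
from .waveforms import SignalTrace

__all__ = [
    "MAX_PUMP_FLOW",
    "ValveLaw",
    "CircuitModel",
    "CircuitState",
    "NoiseSpec",
    "SimResult",
    "valve_resistance",
    "derivatives",
    "steady_state_pressures",
    "steady_state_sensor_pressure",
    "simulate",
    "split_flow",
]

#: Roller-pump capability, mL/min.
MAX_PUMP_FLOW = 600.0


@dataclass(frozen=True)
class ValveLaw:
    """Closure -> hydraulic resistance mapping of the proportional pinch-valve.

    The pinch-valve raises resistance by compressing the silicone tubing
    externally.  No transfer function is available for the physical
    valve, so the twin uses a geometric (log-linear) law

        R(c) = open_resistance * (occluded_resistance / open_resistance) ** (c ** shape_exponent)

    which is strictly increasing and continuous on [0, 1], spans the full
    open->occluded range, and is smooth in log-resistance.  The shape
    exponent bends the log-resistance profile (1 = log-linear).
    """

    open_resistance: float = 0.05  # mmHg*min/mL at closure 0
    occluded_resistance: float = 500.0  # mmHg*min/mL at closure 1
    shape_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.open_resistance <= 0:
            raise ConfigurationError("open_resistance must be > 0")
        if self.occluded_resistance / self.open_resistance < 1.0e4:
            raise ConfigurationError(
                "occluded_resistance must be >= 1e4 * open_resistance"
            )
        if self.shape_exponent <= 0:
            raise ConfigurationError("shape_exponent must be > 0")


def valve_resistance(closure, law: ValveLaw):
    """Valve hydraulic resistance (mmHg*min/mL) at a closure fraction in [0, 1]."""
    c = np.asarray(closure, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("closure must be in [0, 1]")
    ratio = law.occluded_resistance / law.open_resistance
    r = law.open_resistance * ratio ** (c**law.shape_exponent)
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class CircuitModel:
    """Element values and topology switches of one hydraulic circuit.

    ``service_compliance`` of ``None`` selects the compliance-test
    topology (no C_s node, sensor at the algebraic sample-inlet
    junction); a positive value selects the coronary-like topology
    (sensor at the C_s node).  ``reservoir_compliance`` describes the
    vented return stage: its pressure is pinned at
    ``outflow_reference_pressure`` (vented to atmosphere -> 0), so it
    stores no state in the twin.
    """

    pump_flow: float  # mL/min
    reservoir_compliance: float = 2.0  # mL/mmHg (vented return stage)
    filter_compliance: float = 0.01  # mL/mmHg, pump-pulsatility damping
    service_compliance: float | None = None  # mL/mmHg, coronary only
    segment_resistances: tuple[float, float] = (0.05, 0.02)  # feed, return
    sample_resistance: float = 0.05  # mmHg*min/mL per sample branch
    n_parallel_samples: int = 1
    valve_law: ValveLaw = field(default_factory=ValveLaw)
    outflow_reference_pressure: float = 0.0  # mmHg
    pump_ripple_fraction: float = 0.0  # optional roller ripple (off by default)
    pump_ripple_frequency: float = 8.0  # Hz

    def __post_init__(self) -> None:
        errors = []
        if not 0.0 <= self.pump_flow <= MAX_PUMP_FLOW:
            errors.append(f"pump_flow must be in [0, {MAX_PUMP_FLOW}] mL/min")
        if self.reservoir_compliance <= 0:
            errors.append("reservoir_compliance must be > 0")
        if self.filter_compliance <= 0:
            errors.append("filter_compliance must be > 0")
        if self.service_compliance is not None and self.service_compliance <= 0:
            errors.append("service_compliance must be > 0 when present")
        if any(r < 0 for r in self.segment_resistances):
            errors.append("segment_resistances must be >= 0")
        if self.sample_resistance < 0:
            errors.append("sample_resistance must be >= 0")
        if self.n_parallel_samples < 1:
            errors.append("n_parallel_samples must be >= 1")
        if errors:
            raise ConfigurationError("; ".join(errors))

    @classmethod
    def compliance_test(cls, pump_flow: float = 200.0, **kwargs) -> "CircuitModel":
        """Default single-sample pressurization circuit."""
        return cls(pump_flow=pump_flow, service_compliance=None, **kwargs)

    @classmethod
    def coronary(
        cls,
        pump_flow: float = 540.0,
        service_compliance: float = 0.005,
        n_parallel_samples: int = 3,
        filter_compliance: float = 0.02,
        **kwargs,
    ) -> "CircuitModel":
        """Default coronary-like circuit: 540 mL/min split over 3 samples."""
        return cls(
            pump_flow=pump_flow,
            service_compliance=service_compliance,
            n_parallel_samples=n_parallel_samples,
            filter_compliance=filter_compliance,
            **kwargs,
        )

    @property
    def n_nodes(self) -> int:
        return 2 if self.service_compliance is not None else 1

    @property
    def node_compliances(self) -> tuple[float, ...]:
        if self.service_compliance is not None:
            return (self.filter_compliance, self.service_compliance)
        return (self.filter_compliance,)

    @property
    def sample_stage_resistance(self) -> float:
        """Equivalent resistance of the n parallel sample branches."""
        return self.sample_resistance / self.n_parallel_samples

    def downstream_resistance(self, closure: float) -> float:
        """Resistance from the sensor point to the vented reservoir."""
        r_valve = valve_resistance(closure, self.valve_law)
        return self.sample_stage_resistance + self.segment_resistances[1] + r_valve


@dataclass
class CircuitState:
    """Instantaneous state of the network."""

    time: float  # s
    node_pressures: np.ndarray  # mmHg, one per compliance node
    valve_closure: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        self.node_pressures = np.asarray(self.node_pressures, dtype=float)
        if not 0.0 <= self.valve_closure <= 1.0:
            raise ValueError("valve_closure must be in [0, 1]")
        if not np.all(np.isfinite(self.node_pressures)):
            raise ValueError("node pressures must be finite")


def _flows(model: CircuitModel, pressures: np.ndarray, closure: float, q_pump: float):
    """Edge flows (mL/min) and sensor pressure for the current state.

    Returns (flow into node i..., chain outflow, sensor pressure,
    per-branch sample flow).
    """
    r_feed = model.segment_resistances[0]
    p_ref = model.outflow_reference_pressure
    r_down = model.downstream_resistance(closure)
    if model.service_compliance is not None:
        p_f, p_s = pressures
        q_feed = (p_f - p_s) / r_feed if r_feed > 0 else math.nan
        q_out = (p_s - p_ref) / r_down
        sensor = p_s
    else:
        p_f = pressures[0]
        q_out = (p_f - p_ref) / (r_feed + r_down)
        q_feed = q_out
        sensor = p_f - q_out * r_feed
    branch_flow = q_out / model.n_parallel_samples
    return q_feed, q_out, sensor, branch_flow


def derivatives(
    model: CircuitModel, state: CircuitState, pump_flow_at_t: float
) -> np.ndarray:
    """Rate of change of node pressures, mmHg/s.

    Each node obeys conservation: C_i * dP_i/dt = inflow - outflow, with
    flows in mL/min and compliances in mL/mmHg (hence the /60).
    """
    comps = model.node_compliances
    if any(c <= 0 for c in comps):
        raise ConfigurationError("zero compliance at a node")
    q_feed, q_out, _, _ = _flows(
        model, state.node_pressures, state.valve_closure, pump_flow_at_t
    )
    if model.service_compliance is not None:
        dp_f = (pump_flow_at_t - q_feed) / comps[0] / 60.0
        dp_s = (q_feed - q_out) / comps[1] / 60.0
        return np.array([dp_f, dp_s])
    dp_f = (pump_flow_at_t - q_out) / comps[0] / 60.0
    return np.array([dp_f])


def steady_state_pressures(model: CircuitModel, closure: float) -> np.ndarray:
    """Algebraic equilibrium node pressures at constant closure and pump flow.

    In steady state the full pump flow traverses the chain, so pressures
    follow from the Ohm analogue P = Q * R accumulated from the vented
    reservoir upward.
    """
    q = model.pump_flow
    p_ref = model.outflow_reference_pressure
    p_sensor = p_ref + q * model.downstream_resistance(closure)
    p_filter = p_sensor + q * model.segment_resistances[0]
    if model.service_compliance is not None:
        return np.array([p_filter, p_sensor])
    return np.array([p_filter])


def steady_state_sensor_pressure(model: CircuitModel, closure: float) -> float:
    """Equilibrium pressure (mmHg) at the sensor for a constant closure."""
    q = model.pump_flow
    return model.outflow_reference_pressure + q * model.downstream_resistance(closure)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian sensor noise, applied once at acquisition."""

    pressure_sd: float = 0.5  # mmHg
    flow_sd: float = 1.0  # mL/min


@dataclass
class SimResult:
    """Output of an open-loop simulation run."""

    pressure: SignalTrace  # sensor pressure at simulator resolution
    flow: SignalTrace  # per-branch sample flow at simulator resolution
    volume_error: float  # |pumped - returned - stored| / pumped
    final_state: CircuitState


def _pump_flow_at(model: CircuitModel, t: float) -> float:
    """Pump output at time t: constant flow plus optional roller ripple."""
    q = model.pump_flow
    if model.pump_ripple_fraction > 0:
        q = q * (
            1.0
            + model.pump_ripple_fraction
            * math.sin(2.0 * math.pi * model.pump_ripple_frequency * t)
        )
    return q


def simulate(
    model: CircuitModel,
    closure_fn: Callable[[float], float] | float,
    duration: float,
    dt: float = 1e-3,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    initial_state: CircuitState | None = None,
) -> SimResult:
    """Open-loop fixed-step simulation of the circuit.

    ``closure_fn`` is either a constant closure fraction or a callable
    t -> closure.  Returns sensor-pressure and per-branch-flow traces at
    the simulator resolution (1/dt).  Additive Gaussian sensor noise is
    applied to the returned traces when ``noise`` is given; the
    integration itself is always noise-free.

    Raises :class:`SimulationError` naming the offending time if the
    state becomes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if callable(closure_fn):
        closure_at = closure_fn
    else:
        c_const = float(closure_fn)
        closure_at = lambda t: c_const  # noqa: E731
    if initial_state is None:
        pressures = steady_state_pressures(model, closure_at(0.0)).copy()
        t0 = 0.0
    else:
        pressures = initial_state.node_pressures.astype(float).copy()
        t0 = initial_state.time
    comps = np.asarray(model.node_compliances)
    if np.any(comps <= 0):
        raise ConfigurationError("zero compliance at a node")

    n_steps = int(round(duration / dt))
    p_out = np.empty(n_steps)
    q_out_arr = np.empty(n_steps)
    pumped = 0.0
    returned = 0.0
    p_start = pressures.copy()
    t = t0
    for i in range(n_steps):
        c = float(closure_at(t))
        c = min(max(c, 0.0), 1.0)
        q_pump = _pump_flow_at(model, t)
        q_feed, q_chain, sensor, branch = _flows(model, pressures, c, q_pump)
        p_out[i] = sensor
        q_out_arr[i] = branch
        if model.service_compliance is not None:
            pressures[0] += (q_pump - q_feed) / comps[0] / 60.0 * dt
            pressures[1] += (q_feed - q_chain) / comps[1] / 60.0 * dt
        else:
            pressures[0] += (q_pump - q_chain) / comps[0] / 60.0 * dt
        pumped += q_pump * dt
        returned += q_chain * dt
        t = t0 + (i + 1) * dt
        if not np.all(np.isfinite(pressures)):
            raise SimulationError(f"integration diverged at t = {t:.6f} s", time=t)
    stored = float(np.sum(comps * (pressures - p_start))) * 60.0  # mL/min*s units
    volume_error = abs(pumped - returned - stored) / pumped if pumped > 0 else 0.0

    fs = 1.0 / dt
    if noise is not None:
        rng = np.random.default_rng(seed)
        p_out = p_out + rng.normal(0.0, noise.pressure_sd, size=n_steps)
        q_out_arr = q_out_arr + rng.normal(0.0, noise.flow_sd, size=n_steps)
    pressure = SignalTrace(p_out, fs, start_time=t0, kind="pressure", units="mmHg")
    flow = SignalTrace(q_out_arr, fs, start_time=t0, kind="flow", units="mL/min")
    final = CircuitState(time=t, node_pressures=pressures, valve_closure=min(max(float(closure_at(t)), 0.0), 1.0))
    return SimResult(pressure=pressure, flow=flow, volume_error=volume_error, final_state=final)


def split_flow(total: float, n_branches: int) -> float:
    """Per-branch mean flow for ``total`` distributed uniformly over branches.

    The multi-sample chamber's channel geometry distributes inflow
    uniformly over its parallel culture units: 540 mL/min over 3 branches
    gives 180 mL/min per sample.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if total < 0:
        raise ValueError("total flow must be >= 0")
    return total / n_branches
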