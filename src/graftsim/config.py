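"""Experiment configuration: schema, validation, defaults, hashing.

A configuration file (YAML or JSON) fully describes one experiment:
which of the two platform setups to run (``compliance_test`` or
``coronary_run``), the hydraulic element values, the phantom and working
fluid, the controller block, the target pressure regime (one of the
three ISO 7198 regimes, or any user-defined pair including pathological
ones such as isolated diastolic hypotension / isolated systolic
hypertension), the acquisition block, and the imaging block.  All fields
have defaults matching the bench protocol, so a minimal file needs only
``kind``.  Every artifact written by the runners embeds the
configuration hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .circuit import CircuitModel, ValveLaw
from .control import ISO_REGIMES, PIDGains, PressureRegime, SafetyLimits
from .errors import ConfigurationError
from .phantom import FluidSpec, PhantomSpec

__all__ = ["ExperimentConfig", "load_config", "save_config"]


@dataclass
class AcquisitionConfig:
    """Sensor rates, run length, integration step, and noise levels."""

    pressure_rate: float = 40.0  # Hz
    flow_rate: float = 200.0  # Hz
    n_cycles: int = 35
    settle_cycles: int = 5
    dt: float = 1.0e-3  # s, simulator step
    noise_pressure_sd: float = 0.5  # mmHg
    noise_flow_sd: float = 1.0  # mL/min


@dataclass
class ImagingConfig:
    """Synthetic video geometry and degradations."""

    frame_rate: float = 150.0  # fps
    duration: float = 30.0  # s
    mm_per_pixel: float = 0.002
    frame_height: int = 2200
    frame_width: int = 40
    noise_sd: float = 0.01
    jitter_px: float = 1.0
    taper_px: float = 1.0
    n_stations: int = 10
    smooth_passes: int = 3


@dataclass
class ControllerConfig:
    """PID gains, pre-setting tolerance and safety limits."""

    kp: float = 8.0e-4
    ki: float = 1.8e-3
    kd: float = 0.0
    anti_windup_limit: float = 300.0
    error_filter_alpha: float = 0.7
    max_step: float = 0.05
    tolerance: float = 2.0  # mmHg, pre-setting / tracking tolerance
    safety_pressure_min: float = 5.0  # mmHg
    safety_pressure_max: float = 250.0  # mmHg

    def gains(self) -> PIDGains:
        return PIDGains(
            kp=self.kp,
            ki=self.ki,
            kd=self.kd,
            anti_windup_limit=self.anti_windup_limit,
            error_filter_alpha=self.error_filter_alpha,
            max_step=self.max_step,
        )

    def safety(self) -> SafetyLimits:
        return SafetyLimits(
            pressure_max=self.safety_pressure_max,
            pressure_min=self.safety_pressure_min,
        )


@dataclass
class RegimeConfig:
    """Pressure regime block: named ISO regime or explicit pair."""

    name: str | None = "normotension"
    p_min: float | None = None
    p_max: float | None = None
    frequency: float = 1.0
    systole_duration: float = 0.35  # s, coronary motion law

    def regime(self, tolerance: float) -> PressureRegime:
        if self.p_min is not None and self.p_max is not None:
            lo, hi = self.p_min, self.p_max
        elif self.name is not None:
            if self.name not in ISO_REGIMES:
                raise ConfigurationError(
                    f"regime.name must be one of {sorted(ISO_REGIMES)} "
                    "or p_min/p_max must be given"
                )
            lo, hi = ISO_REGIMES[self.name]
        else:
            raise ConfigurationError("regime requires a name or p_min/p_max")
        return PressureRegime(lo, hi, frequency=self.frequency, tolerance=tolerance)


@dataclass
class CircuitConfig:
    """Hydraulic element values; ``None`` pump flow picks the kind default."""

    pump_flow: float | None = None
    reservoir_compliance: float = 2.0
    filter_compliance: float | None = None
    service_compliance: float | None = None
    segment_resistances: tuple[float, float] = (0.05, 0.02)
    sample_resistance: float = 0.05
    n_parallel_samples: int | None = None
    valve_open_resistance: float = 0.05
    valve_occluded_resistance: float = 500.0
    valve_shape_exponent: float = 1.0
    outflow_reference_pressure: float = 0.0
    pump_ripple_fraction: float = 0.0

    def model(self, kind: str) -> CircuitModel:
        law = ValveLaw(
            open_resistance=self.valve_open_resistance,
            occluded_resistance=self.valve_occluded_resistance,
            shape_exponent=self.valve_shape_exponent,
        )
        common = dict(
            reservoir_compliance=self.reservoir_compliance,
            segment_resistances=tuple(self.segment_resistances),
            sample_resistance=self.sample_resistance,
            valve_law=law,
            outflow_reference_pressure=self.outflow_reference_pressure,
            pump_ripple_fraction=self.pump_ripple_fraction,
        )
        if kind == "coronary_run":
            return CircuitModel.coronary(
                pump_flow=self.pump_flow if self.pump_flow is not None else 540.0,
                service_compliance=(
                    self.service_compliance
                    if self.service_compliance is not None
                    else 0.005
                ),
                n_parallel_samples=(
                    self.n_parallel_samples
                    if self.n_parallel_samples is not None
                    else 3
                ),
                filter_compliance=(
                    self.filter_compliance
                    if self.filter_compliance is not None
                    else 0.02
                ),
                **common,
            )
        return CircuitModel.compliance_test(
            pump_flow=self.pump_flow if self.pump_flow is not None else 200.0,
            filter_compliance=(
                self.filter_compliance if self.filter_compliance is not None else 0.01
            ),
            n_parallel_samples=(
                self.n_parallel_samples if self.n_parallel_samples is not None else 1
            ),
            **common,
        )


@dataclass
class PhantomConfig:
    inner_diameter_ref: float = 3.227
    wall_thickness: float = 0.4
    length: float = 50.0
    distension_coeff: float = 7.548973e-05
    reference_pressure: float = 79.67

    def spec(self) -> PhantomSpec:
        return PhantomSpec(
            inner_diameter_ref=self.inner_diameter_ref,
            wall_thickness=self.wall_thickness,
            length=self.length,
            distension_coeff=self.distension_coeff,
            reference_pressure=self.reference_pressure,
        )


@dataclass
class FluidConfig:
    glycerol_mass_fraction: float = 0.50
    temperature: float = 37.0

    def spec(self) -> FluidSpec:
        return FluidSpec(
            glycerol_mass_fraction=self.glycerol_mass_fraction,
            temperature=self.temperature,
        )


_KINDS = ("compliance_test", "coronary_run")


@dataclass
class ExperimentConfig:
    """Top-level experiment description."""

    kind: str = "compliance_test"
    seed: int = 0
    n_timepoints: int = 1  # seeded repeats emulating multi-day runs
    circuit: CircuitConfig = field(default_factory=CircuitConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    regime: RegimeConfig = field(default_factory=RegimeConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    def validate(self) -> None:
        """Validate the whole tree, reporting every failing field at once."""
        errors: list[str] = []
        if self.kind not in _KINDS:
            errors.append(f"kind: must be one of {_KINDS}")
        if self.n_timepoints < 1:
            errors.append("n_timepoints: must be >= 1")
        if self.seed < 0:
            errors.append("seed: must be >= 0")
        try:
            regime = self.regime.regime(self.controller.tolerance)
        except (ConfigurationError, Exception) as exc:  # collect, don't raise
            errors.append(f"regime: {exc}")
            regime = None
        if regime is not None and self.regime.systole_duration >= regime.period:
            errors.append("regime.systole_duration: must be < regime period")
        try:
            self.circuit.model(self.kind if self.kind in _KINDS else "compliance_test")
        except Exception as exc:
            errors.append(f"circuit: {exc}")
        try:
            self.phantom.spec()
        except Exception as exc:
            errors.append(f"phantom: {exc}")
        try:
            self.fluid.spec()
        except Exception as exc:
            errors.append(f"fluid: {exc}")
        try:
            self.controller.gains()
            self.controller.safety()
        except Exception as exc:
            errors.append(f"controller: {exc}")
        acq = self.acquisition
        if acq.pressure_rate <= 0 or acq.flow_rate <= 0:
            errors.append("acquisition: rates must be > 0")
        if acq.dt <= 0 or acq.dt > 1.0 / max(acq.pressure_rate, acq.flow_rate):
            errors.append("acquisition.dt: must be > 0 and below sensor intervals")
        if acq.n_cycles <= acq.settle_cycles:
            errors.append("acquisition.n_cycles: must exceed settle_cycles")
        img = self.imaging
        if img.frame_rate <= 0 or img.duration <= 0 or img.mm_per_pixel <= 0:
            errors.append("imaging: frame_rate, duration, mm_per_pixel must be > 0")
        if errors:
            raise ConfigurationError(
                "invalid configuration:\n  " + "\n  ".join(errors)
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        """Short provenance hash of the canonicalised configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        sub = {
            "circuit": CircuitConfig,
            "phantom": PhantomConfig,
            "fluid": FluidConfig,
            "controller": ControllerConfig,
            "regime": RegimeConfig,
            "acquisition": AcquisitionConfig,
            "imaging": ImagingConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sub:
                if not isinstance(value, dict):
                    raise ConfigurationError(f"{key}: must be a mapping")
                unknown = set(value) - {f for f in sub[key].__dataclass_fields__}
                if unknown:
                    raise ConfigurationError(
                        f"{key}: unknown fields {sorted(unknown)}"
                    )
                if "segment_resistances" in value:
                    value = {**value, "segment_resistances": tuple(value["segment_resistances"])}
                kwargs[key] = sub[key](**value)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown top-level field {key!r}")
        return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load, default-fill and validate an experiment configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ConfigurationError(f"unsupported config format: {path.suffix}")
    cfg = ExperimentConfig.from_dict(data)
    cfg.validate()
    return cfg


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a configuration back to YAML or JSON (round-trip safe)."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise ConfigurationError(f"unsupported config format: {path.suffix}")
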