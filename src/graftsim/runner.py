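"""End-to-end experimental procedures chaining the library modules.

``run_compliance_test`` reproduces the automated compliance protocol:
pre-setting, PID-regulated sinusoidal pressurisation of the phantom,
quasi-static distension, synthetic video rendering, and the image-based
compliance pipeline, reported in the bench table layout (Pmin, Pmax,
deltaP, DPmin, DPmax, C).

``run_coronary`` reproduces the coronary-like stimulation protocol:
pre-setting, PID-regulated piecewise valve motion with the service
compliance in circuit, acquisition at 40/200 Hz, 3-point filtering,
per-cycle metrics, counter-phase characterisation, and (for multi-day
emulations) Welch-ANOVA stability statistics across seeded timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as gio
from .circuit import NoiseSpec
from .config import ExperimentConfig
from .control import StimulationResult, run_regulated_stimulation
from .errors import ConfigurationError
from .imaging import ComplianceResult, compliance_pipeline, render_frames
from .phantom import diameter_at_pressure
from .waveforms import (
    CycleMetrics,
    SignalTrace,
    StabilityReport,
    counterphase_index,
    cycle_metrics,
    detect_cycles,
    moving_average_3,
    stability_analysis,
)

__all__ = [
    "run_compliance_test",
    "run_coronary",
    "ComplianceRunOutput",
    "CoronaryRunOutput",
]


def _stimulate(cfg: ExperimentConfig, law_kind: str, seed: int) -> StimulationResult:
    model = cfg.circuit.model(cfg.kind)
    regime = cfg.regime.regime(cfg.controller.tolerance)
    acq = cfg.acquisition
    return run_regulated_stimulation(
        model,
        regime,
        law_kind=law_kind,
        gains=cfg.controller.gains(),
        n_cycles=acq.n_cycles,
        seed=seed,
        dt=acq.dt,
        settle_cycles=acq.settle_cycles,
        noise=NoiseSpec(pressure_sd=acq.noise_pressure_sd, flow_sd=acq.noise_flow_sd),
        safety=cfg.controller.safety(),
        systole_duration=cfg.regime.systole_duration,
        pressure_rate=acq.pressure_rate,
        flow_rate=acq.flow_rate,
    )


def _post_settle(trace: SignalTrace, t0: float) -> SignalTrace:
    """Slice a trace to times >= t0 (start of the analysis window)."""
    n_skip = int(round((t0 - trace.start_time) * trace.sampling_rate))
    n_skip = max(0, min(n_skip, len(trace)))
    return SignalTrace(
        trace.samples[n_skip:],
        trace.sampling_rate,
        start_time=trace.start_time + n_skip / trace.sampling_rate,
        kind=trace.kind,
        units=trace.units,
    )


@dataclass
class ComplianceRunOutput:
    result: ComplianceResult
    stimulation: StimulationResult
    metrics: CycleMetrics
    report: dict


def run_compliance_test(
    cfg: ExperimentConfig, outdir: str | Path | None = None,
    write_frames: bool = False,
) -> ComplianceRunOutput:
    """Automated compliance characterisation on the configured phantom."""
    if cfg.kind != "compliance_test":
        raise ConfigurationError("configuration kind must be compliance_test")
    cfg.validate()
    acq = cfg.acquisition
    img = cfg.imaging
    regime = cfg.regime.regime(cfg.controller.tolerance)
    stim = _stimulate(cfg, "sinusoidal", cfg.seed)
    if stim.aborted:
        raise ConfigurationError(
            f"run aborted by safety interlock at t={stim.abort_time:.2f} s"
        )

    t0 = acq.settle_cycles * regime.period
    window = min(img.duration, stim.pressure_highres.duration - t0)

    # phantom distension follows the true (noise-free) luminal pressure
    p_hi = _post_settle(stim.pressure_highres, t0)
    spec = cfg.phantom.spec()
    n_frames = int(window * img.frame_rate)
    t_frames = t0 + np.arange(n_frames) / img.frame_rate
    p_at_frames = np.interp(t_frames, p_hi.times, p_hi.samples)
    _, outer = diameter_at_pressure(spec, p_at_frames)
    stack = render_frames(
        outer,
        img.mm_per_pixel,
        frame_shape=(img.frame_height, img.frame_width),
        frame_rate=img.frame_rate,
        noise_sd=img.noise_sd,
        jitter_px=img.jitter_px,
        taper_px=img.taper_px,
        seed=cfg.seed + 1,
        start_time=t0,
    )
    pressure = _post_settle(stim.pressure, t0)
    result = compliance_pipeline(
        stack,
        pressure,
        spec,
        nominal_period=regime.period,
        n_stations=img.n_stations,
        smooth_passes=img.smooth_passes,
    )
    boundaries = detect_cycles(moving_average_3(pressure), regime.period)
    metrics = cycle_metrics(pressure, None, boundaries)
    report = {
        "configuration": "compliance_test",
        "config_hash": cfg.hash,
        "seed": cfg.seed,
        "regime": {
            "p_min_target": regime.p_min_target,
            "p_max_target": regime.p_max_target,
            "frequency_hz": regime.frequency,
        },
        "table": {
            "Pmin_mmHg": metrics.aggregates["p_min"],
            "Pmax_mmHg": metrics.aggregates["p_max"],
            "dP_mmHg": metrics.aggregates["dp"],
            "DPmin_mm": result.DPmin,
            "DPmax_mm": result.DPmax,
            "C_mean": result.C_mean,
            "C_sd": result.C_sd,
        },
        "n_cycles": result.n_cycles,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_trace(stim.pressure, outdir / "pressure_40hz.csv", cfg.seed, cfg.hash)
        stim.controller_log.to_csv(outdir / "controller_log.csv", index=False)
        gio.write_report(report, outdir / "compliance_report.json")
        if write_frames:
            gio.write_frames(stack, outdir / "frames.tiff")
    return ComplianceRunOutput(
        result=result, stimulation=stim, metrics=metrics, report=report
    )


@dataclass
class CoronaryRunOutput:
    metrics: CycleMetrics
    stimulation: StimulationResult
    lag: float
    diastolic_flow_fraction: float
    stability: StabilityReport | None
    report: dict


def run_coronary(
    cfg: ExperimentConfig, outdir: str | Path | None = None
) -> CoronaryRunOutput:
    """Coronary-like stimulation, optionally over several seeded timepoints."""
    if cfg.kind != "coronary_run":
        raise ConfigurationError("configuration kind must be coronary_run")
    cfg.validate()
    acq = cfg.acquisition
    regime = cfg.regime.regime(cfg.controller.tolerance)

    per_day: list[CycleMetrics] = []
    first_stim = None
    lag = frac = None
    for day in range(cfg.n_timepoints):
        stim = _stimulate(cfg, "coronary_piecewise", cfg.seed + 1000 * day)
        if stim.aborted:
            raise ConfigurationError(
                f"run aborted by safety interlock at t={stim.abort_time:.2f} s"
            )
        t0 = acq.settle_cycles * regime.period
        pressure = _post_settle(stim.pressure, t0)
        flow = _post_settle(stim.flow, t0)
        boundaries = detect_cycles(moving_average_3(pressure), regime.period)
        metrics = cycle_metrics(pressure, flow, boundaries)
        per_day.append(metrics)
        if day == 0:
            first_stim = stim
            lag, frac = counterphase_index(
                pressure,
                flow,
                systole_duration=cfg.regime.systole_duration,
                nominal_period=regime.period,
            )
    stability = (
        stability_analysis(per_day) if cfg.n_timepoints > 1 else None
    )
    metrics = per_day[0]
    report = {
        "configuration": "coronary_run",
        "config_hash": cfg.hash,
        "seed": cfg.seed,
        "n_timepoints": cfg.n_timepoints,
        "table": {
            "Pmin_mmHg": metrics.aggregates["p_min"],
            "Pmax_mmHg": metrics.aggregates["p_max"],
            "dP_mmHg": metrics.aggregates["dp"],
            "Qmean_mL_min": metrics.aggregates["q_mean"],
            "dQ_mL_min": metrics.aggregates["dq"],
        },
        "counterphase": {
            "lag_s": lag,
            "diastolic_flow_fraction": frac,
        },
        "n_cycles": metrics.n_cycles,
    }
    if stability is not None:
        report["stability"] = {
            "summary": stability.summary,
            "welch_anova": stability.anova,
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_trace(
            first_stim.pressure, outdir / "pressure_40hz.csv", cfg.seed, cfg.hash
        )
        gio.write_trace(first_stim.flow, outdir / "flow_200hz.csv", cfg.seed, cfg.hash)
        first_stim.controller_log.to_csv(outdir / "controller_log.csv", index=False)
        gio.write_report(report, outdir / "coronary_report.json")
    return CoronaryRunOutput(
        metrics=metrics,
        stimulation=first_stim,
        lag=lag,
        diastolic_flow_fraction=frac,
        stability=stability,
        report=report,
    )
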