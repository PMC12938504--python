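"""Signal acquisition emulation and cycle-wise hemodynamic analytics.

This module owns the uniformly sampled trace container and everything the
bench analysis does to pressure/flow recordings: decimation to the sensor
rates (pressure 40 Hz, flow 200 Hz), the 3-point moving-average filter
applied before any analysis, pressure-minimum cycle detection, per-cycle
extremes/means, the counter-phase characterisation of coronary-like runs,
and the Welch heteroscedastic one-way ANOVA used for long-term stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DetectionError

__all__ = [
    "SignalTrace",
    "CycleMetrics",
    "StabilityReport",
    "acquire",
    "moving_average_3",
    "detect_cycles",
    "cycle_metrics",
    "counterphase_index",
    "welch_anova",
    "stability_analysis",
]


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled time series (pressure in mmHg or flow in mL/min)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    start_time: float = 0.0  # s
    kind: str = "pressure"  # "pressure" | "flow"
    units: str = "mmHg"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.kind not in ("pressure", "flow"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Samples with absolute timestamps in [t0, t1)."""
        t = self.times
        return self.samples[(t >= t0) & (t < t1)]


def acquire(
    trace: SignalTrace,
    target_rate: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SignalTrace:
    """Emulate sensor acquisition: resample to ``target_rate`` and add noise.

    The simulator produces traces at its integration resolution; the bench
    sensors sample pressure at 40 Hz and flow at 200 Hz.  When the source
    rate is an integer multiple of the target rate the trace is decimated
    by stride, otherwise it is linearly interpolated.  Gaussian sensor
    noise (if any) is applied here exactly once.
    """
    if target_rate > trace.sampling_rate:
        raise ValueError(
            f"target_rate {target_rate} Hz exceeds source rate {trace.sampling_rate} Hz"
        )
    ratio = trace.sampling_rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        samples = trace.samples[:: int(round(ratio))].copy()
    else:
        n_out = int(np.floor(trace.duration * target_rate))
        t_out = np.arange(n_out) / target_rate
        samples = np.interp(t_out, trace.times - trace.start_time, trace.samples)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=samples.shape)
    return replace(trace, samples=samples, sampling_rate=target_rate)


def moving_average_3(trace: SignalTrace) -> SignalTrace:
    """3-point moving average, as applied to all bench signals before analysis.

    Interior sample i becomes the mean of samples i-1, i, i+1.  Edge rule:
    endpoints are averaged over their available neighbours (2-point means),
    so the output length equals the input length.
    """
    x = trace.samples
    if len(x) < 3:
        raise ValueError("moving_average_3 requires at least 3 samples")
    out = np.convolve(x, np.ones(3) / 3.0, mode="same")
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return replace(trace, samples=out)


def detect_cycles(pressure: SignalTrace, nominal_period: float) -> np.ndarray:
    """Cycle boundary times from successive pressure minima.

    Boundaries anchor at pressure minima (the controller is
    pressure-referenced and each stimulation cycle starts at minimal valve
    closure, i.e. at the pressure minimum).  Minima must be spaced within
    +-25% of ``nominal_period``.  Returns boundary times in seconds
    (same clock as ``pressure.start_time``).
    """
    x = pressure.samples
    fs = pressure.sampling_rate
    if pressure.duration < 2 * nominal_period:
        raise DetectionError("trace must span at least two nominal periods")
    amplitude = float(np.ptp(x))
    if amplitude <= 0:
        raise DetectionError("no periodicity found: trace is constant")
    distance = max(1, int(0.75 * nominal_period * fs))
    minima, _ = sps.find_peaks(-x, distance=distance, prominence=0.1 * amplitude)
    if len(minima) < 2:
        raise DetectionError("no periodicity found: fewer than two pressure minima")
    spacing = np.diff(minima) / fs
    ok = (spacing > 0.75 * nominal_period) & (spacing < 1.25 * nominal_period)
    if not np.any(ok):
        raise DetectionError(
            "no periodicity found: minima spacing inconsistent with nominal period"
        )
    return pressure.start_time + minima / fs


@dataclass(frozen=True)
class CycleMetrics:
    """Per-cycle hemodynamic metrics plus aggregates (mean +- SD over cycles).

    ``per_cycle`` has one row per cycle with columns p_min, p_max, dp and,
    when a flow trace was supplied, q_mean, q_min, q_max, dq.  By
    construction dp = p_max - p_min and dq = q_max - q_min hold exactly
    per cycle.
    """

    per_cycle: pd.DataFrame
    aggregates: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.per_cycle)

    def table_row(self) -> dict:
        """Mean +- SD summary in the bench-report column layout."""
        return dict(self.aggregates)


def cycle_metrics(
    pressure: SignalTrace,
    flow: SignalTrace | None,
    boundaries: Sequence[float],
) -> CycleMetrics:
    """Per-cycle extremes/means on 3-point-filtered traces.

    ``boundaries`` are cycle boundary times as returned by
    :func:`detect_cycles`; cycle k spans [boundaries[k], boundaries[k+1]).
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if len(boundaries) < 2:
        raise ValueError("need at least one complete cycle (two boundaries)")
    t0, t1 = pressure.start_time, pressure.start_time + pressure.duration
    if boundaries[0] < t0 - 1e-9 or boundaries[-1] > t1 + 1e-9:
        raise ValueError("cycle boundary outside the pressure trace")
    p = moving_average_3(pressure)
    q = moving_average_3(flow) if flow is not None else None
    rows = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        ps = p.window(a, b)
        if len(ps) == 0:
            raise ValueError("empty cycle window in pressure trace")
        row = {
            "p_min": float(ps.min()),
            "p_max": float(ps.max()),
        }
        row["dp"] = row["p_max"] - row["p_min"]
        if q is not None:
            qs = q.window(a, b)
            if len(qs) == 0:
                raise ValueError("empty cycle window in flow trace")
            row.update(
                q_mean=float(qs.mean()),
                q_min=float(qs.min()),
                q_max=float(qs.max()),
            )
            row["dq"] = row["q_max"] - row["q_min"]
        rows.append(row)
    per_cycle = pd.DataFrame(rows)
    aggregates = {
        col: (float(per_cycle[col].mean()), float(per_cycle[col].std(ddof=1)))
        for col in per_cycle.columns
    }
    return CycleMetrics(per_cycle=per_cycle, aggregates=aggregates)


def counterphase_index(
    pressure: SignalTrace,
    flow: SignalTrace,
    systole_duration: float = 0.35,
    nominal_period: float = 1.0,
) -> tuple[float, float]:
    """Counter-phase characterisation of a coronary-like run.

    Returns ``(lag, diastolic_flow_fraction)``:

    * ``lag`` (s) is the cross-correlation peak between the mean-removed
      pressure and flow, restricted to (-period/2, period/2].  A nonzero
      lag indicates the two signals are out of phase; positive lag means
      flow trails pressure.
    * ``diastolic_flow_fraction`` is the share of per-cycle flow volume
      delivered outside the systolic window (the first
      ``systole_duration`` seconds after each cycle start), in [0, 1].
      Diastolic-dominant perfusion gives a fraction > 0.5.
    """
    if abs(pressure.duration - flow.duration) > 2.0 / min(
        pressure.sampling_rate, flow.sampling_rate
    ):
        raise ValueError("pressure and flow traces have mismatched durations")
    boundaries = detect_cycles(moving_average_3(pressure), nominal_period)
    if len(boundaries) < 6:
        raise ValueError("need at least 5 complete cycles")
    period = float(np.mean(np.diff(boundaries)))

    # resample flow onto the pressure clock
    fs = pressure.sampling_rate
    t = pressure.times
    qf = np.interp(t, flow.times, flow.samples)
    pf = pressure.samples - pressure.samples.mean()
    qf = qf - qf.mean()
    corr = sps.correlate(qf, pf, mode="full")
    lags = sps.correlation_lags(len(qf), len(pf), mode="full") / fs
    mask = (lags > -period / 2.0) & (lags <= period / 2.0)
    lag = float(lags[mask][np.argmax(corr[mask])])

    q = moving_average_3(flow)
    fractions = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        total = q.window(a, b)
        syst = q.window(a, a + systole_duration)
        if len(total) == 0:
            continue
        v_total = float(np.sum(total))  # uniform dt: proportional to volume
        v_syst = float(np.sum(syst))
        if v_total > 0:
            fractions.append(1.0 - v_syst / v_total)
    if not fractions:
        raise ValueError("no complete cycles with flow data")
    return lag, float(np.mean(fractions))


def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA across groups of values.

    Returns ``(F, p)``.  Each group needs at least two values and nonzero
    variance.  With two groups the p-value equals Welch's two-sample
    t-test and F = t^2.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if np.var(g) == 0:
            raise ValueError(f"group {i} has zero variance")
    import pingouin as pg

    data = pd.DataFrame(
        {
            "value": np.concatenate([np.asarray(g, dtype=float) for g in groups]),
            "group": np.concatenate(
                [np.full(len(g), i) for i, g in enumerate(groups)]
            ),
        }
    )
    res = pg.welch_anova(data=data, dv="value", between="group")
    p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
    return float(res["F"].iloc[0]), float(res[p_col].iloc[0])


@dataclass(frozen=True)
class StabilityReport:
    """Long-term stability summary across repeated timepoints.

    ``summary`` has one row per timepoint with the mean +- SD of each
    metric; ``anova`` has one row per metric with Welch's F, the p-value,
    and a significance flag at alpha = 0.05.
    """

    summary: pd.DataFrame
    anova: pd.DataFrame
    alpha: float = 0.05

    @property
    def any_significant(self) -> bool:
        return bool(self.anova["significant"].any())


#: Metrics compared across timepoints in the long-term stability analysis.
STABILITY_METRICS = ("p_min", "p_max", "dp", "q_mean", "dq")


def stability_analysis(
    metrics_by_timepoint: Sequence[CycleMetrics],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> StabilityReport:
    """Welch's ANOVA on per-cycle metric values grouped by timepoint.

    The group sample for each timepoint is the set of per-cycle values
    from that day's acquisition, mirroring a per-timepoint mean +- SD
    summary table.
    """
    if labels is None:
        labels = [f"day_{i}" for i in range(len(metrics_by_timepoint))]
    summary_rows = []
    for label, cm in zip(labels, metrics_by_timepoint):
        row = {"timepoint": label, "n_cycles": cm.n_cycles}
        for m, (mean, sd) in cm.aggregates.items():
            row[f"{m}_mean"] = mean
            row[f"{m}_sd"] = sd
        summary_rows.append(row)
    anova_rows = []
    for m in STABILITY_METRICS:
        if not all(m in cm.per_cycle.columns for cm in metrics_by_timepoint):
            continue
        groups = [cm.per_cycle[m].to_numpy() for cm in metrics_by_timepoint]
        F, p = welch_anova(groups)
        anova_rows.append(
            {"metric": m, "F": F, "p": p, "significant": bool(p < alpha)}
        )
    return StabilityReport(
        summary=pd.DataFrame(summary_rows),
        anova=pd.DataFrame(anova_rows),
        alpha=alpha,
    )
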