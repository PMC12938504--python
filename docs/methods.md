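# Methods

This note documents the models behind `graftsim`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions.  Units are fixed throughout the
package: pressure in mmHg, flow in mL/min, time in s, hydraulic
resistance in mmHg·min/mL, compliance in mL/mmHg, diameters in mm,
viscosity in mPa·s, wall shear stress in Pa.

## Hydraulic circuit model

Each perfusion circuit is a series chain driven by a roller pump
modelled as an ideal volumetric flow source (capability 600 mL/min;
optional sinusoidal roller ripple, off by default because the damping
stage exists precisely to remove it):

    pump → [filter node, C_f] → R_feed → [service node, C_s]* → R_sample/n → R_return + R_valve(c) → vented reservoir

The starred service node exists only in the coronary-like
configuration.  The reservoir is vented to atmosphere, so its pressure
is pinned at the outflow reference (0 mmHg) and its compliance stores
no state.  Node pressures obey conservation, C·dP/dt = ΣQ_in − ΣQ_out;
with flows in mL/min and compliance in mL/mmHg a factor 1/60 converts
the rate to mmHg/s.  In the compliance-test topology the sensor sits at
the algebraic junction downstream of R_feed (no storage there), so the
sensed pressure responds instantaneously to valve motion while the
filter node supplies the volume.

**Element values are calibration choices, not measurements** — the
physical platform's tubing resistances, compliance volumes and valve
transfer function are not available.  Defaults were sized once so that:

* 180 mL/min through a sample branch drops ≈ 9 mmHg
  (R_sample = 0.05 mmHg·min/mL per branch), a physiological
  small-vessel pressure drop;
* all three ISO regimes (50–90, 80–120, 110–150 mmHg) and the coronary
  operating point are reachable with valve closures well inside [0, 1];
* the network's fastest time constant (~2 s at the operating point)
  stays far above the 1 ms integration step, keeping fixed-step
  explicit Euler stable with large margin.  Euler's symmetric flow
  bookkeeping conserves volume to round-off (checked on every run).

Defaults: C_f = 0.01 mL/mmHg (compliance test) or 0.02 (coronary),
C_s = 0.005 mL/mmHg, R_feed = 0.05, R_return = 0.02 mmHg·min/mL,
pump 200 mL/min (compliance test) or 540 mL/min over 3 branches
(coronary).  C_s is deliberately config-exposed: enlarging it deepens
the diastolic flow surge and softens the systolic pressure rise, which
is the platform's own tuning knob for waveform shape.

**Valve law.**  The pinch-valve compresses tubing externally; no
transfer function is published for it, so the twin uses a geometric
(log-linear) law R(c) = R_open·(R_occ/R_open)^(c^k) with
R_open = 0.05, R_occ = 500 (ratio 10⁴, effectively occluding), k = 1.
It is strictly increasing, continuous, spans the full range, and is
smooth in log-resistance — a plausible shape for progressive lumen
collapse.  Any strictly monotone law can be substituted via the config.

## Valve control

The control algorithm copies the platform's two stages.

**Pre-setting** ramps the closure upward from fully open in steps of
0.002, evaluating the steady-state sensor pressure (algebraically — the
steady chain obeys the Ohm analogue P = Q·ΣR); the first step that
crosses a target brackets it and bisection refines to a tenth of the
regime tolerance, giving the PID a tight starting envelope.  P_min is
located first, then the ramp continues for P_max.  Unreachable targets
(below the valve-open pressure or above the fully-closed pressure)
yield a diagnostic non-convergence, not an exception.

**Regulated stimulation** drives the valve with the motion law scaled
between the two commanded envelope closures, initialised at the
pre-set values.  Because the network is dynamic, the extremes reached
during cycling undershoot the steady-state values (the half-sine
systole excites the plant for only 35% of the coronary cycle), so two
discrete PID loops — one per envelope edge, running once per cycle on
the per-cycle extremes of the 3-point-filtered 40 Hz sensor stream —
absorb the difference.  Design choices that matter:

* *Gain scheduling.*  With the log-linear valve law the steady
  sensitivity dP/dc grows in proportion to the pressure excess over the
  valve-open baseline, so fixed gains that are stable at 120 mmHg
  oscillate at 150 mmHg.  Both edges' gains are scaled by
  100 mmHg / (P_max_target − P_open), where P_open is the steady
  pressure at closure 0 (observable at the start of the pre-setting
  ramp).  The lower edge is tracked more stiffly by the plant and
  tolerates less loop gain, so it deliberately shares the upper edge's
  (smaller) scale factor.
* *Error smoothing.*  The per-cycle loop's destabilising mode is
  cycle-to-cycle alternation, which a derivative term would amplify;
  instead the per-cycle error is smoothed with an exponential moving
  average (weight 0.7 on the newest error) before the PID.
* *Defaults* kp = 8·10⁻⁴, ki = 1.8·10⁻³ closure/mmHg per cycle,
  kd = 0, anti-windup clamp ±300 mmHg·cycle, slew limit 0.05
  closure/cycle with conditional integration while clamped.  With
  these, per-cycle extremes settle to within the 2 mmHg tolerance in at
  most 5 cycles and stay there, across all three ISO regimes, the
  coronary law, and sensor-noise seeds (worst observed post-settling
  deviation ≈ 1.5 mmHg over 32 seeded runs).
* *Tolerance.*  The platform's "specified tolerance" is not quantified
  anywhere; 2 mmHg is this package's default, consistent with the
  ±1–2 mmHg per-cycle spreads the bench reports.
* *Phase convention.*  Cycles start at minimal closure: the pressure
  minimum for the sinusoidal law, diastole start for the coronary law.
  The PID acts on per-cycle extremes (envelope correction) rather than
  continuously within the cycle; the source workflow is ambiguous on
  this point and the per-cycle reading is the simplest one consistent
  with correcting a cyclic waveform.

The safety interlock checks every acquired pressure sample against a
configured window (default 5–250 mmHg); a breach zeroes the pump, opens
the valve, and returns the truncated, flagged traces.

## Phantom mechanics and fluid properties

The test article is a silicone tube of 3.2 mm inner diameter and
0.4 mm wall.  Its pressure–diameter behaviour is linearised:
D(p) = D_ref·(1 + α(p − p_ref)), with the default (α = 7.549·10⁻⁵
mmHg⁻¹ at p_ref = 79.67 mmHg) calibrated so the normotensive anchor
pair (3.227 mm at 79.67 mmHg, 3.237 mm at 120.72 mmHg) is reproduced
exactly.  Rationale: the two-point compliance definition only ever
samples the law at two pressures, and over a single 40 mmHg window the
bench data are near-linear.  Consequences worth knowing:

* For a diameter-linear phantom the two-point compliance
  C = α·10⁴/(1 + α(P_min − p_ref)) *decreases* slightly (~0.2%/regime)
  as the regime's operating pressure rises, because the reference
  diameter in the denominator grows.  The increasing C the real
  phantom shows across regimes is a material-nonlinearity signature
  that the linear model intentionally does not reproduce (hyperelastic
  walls are out of scope).
* Coupling is quasi-static (diameter follows pressure instantly, no
  viscoelastic lag) and the wall thickness is held constant under
  pressurisation, so outer = inner + 0.8 mm always.

Working-fluid viscosity uses the Cheng (2008) glycerol–water
correlation (weighted geometric mean of the pure-component
viscosities; valid 0–100 °C), giving 3.40 mPa·s at 50% (w/w), 37 °C.
Wall shear stress is the Poiseuille estimate τ = 4μQ/(πr³) — valid for
fully developed laminar flow in a straight rigid tube, reported as the
cycle-mean value only (no oscillatory shear index).

## Synthetic video and the compliance pipeline

`render_frames` rasterises the phantom as a bright horizontal band on a
dark background: area-coverage anti-aliased edges, the band centred on
a half-integer row (so a noiseless band spans an odd pixel count within
one pixel of D/mm_per_pixel, identical in every column), optional
Gaussian pixel noise, optional per-frame rigid vertical jitter (drawn
continuously, so it carries a subpixel part), and an optional fixed
linear taper across the image width.  Ground-truth diameters and
offsets go into the stack metadata.

The measurement pipeline follows the bench procedure exactly:
phase-correlation registration to the first frame, Otsu binarization,
vertical pixel counts at ten stations at column fractions (i+0.5)/10,
station average per frame, per-cycle extremes → Eq-style two-point
compliance with that cycle's measured (filtered) pressure extremes,
mean ± SD over cycles.  Pixel counting uses the total foreground count
per column; fixtures are rendered hole-free so this coincides with the
longest-run reading.

**Precision is the central difficulty.**  One normotensive pulse
distends the phantom by ≈ 0.010 mm — a single pixel at the 0.01 mm/px
scale — so a binarized pixel-count estimator can only resolve the
excursion through averaging of *dithered* quantisation errors.  Three
generator/pipeline features work together:

* the static taper (default 1 px across the width) staggers the
  subpixel phases of the ten stations, decorrelating their rounding;
* the subpixel part of the per-frame jitter dithers all edges across
  frames and cycles (registration is deliberately integer-precision so
  this dither survives alignment; the difference-of-roundings then has
  exactly zero mean under uniform subpixel phase);
* the per-frame diameter series is smoothed with 3 passes of the same
  3-point moving average used for the bench signals before per-cycle
  extremes are taken, suppressing the positive bias that taking a max
  over dithered counts would otherwise incur.

The default fixtures use 0.002 mm/px (12 s at 50 fps, pixel noise SD
0.01 of the intensity range, jitter SD 1 px), where the recovered
C_mean lands within 2% of ground truth across C* ∈ [0.3, 1.5]·10⁻²
%/mmHg (worst observed 1.1% over 10 seeded fixtures).  Measured
degradation at coarser scales, C* = 0.3 being the worst case
(ΔD ≈ 0.4 px at 0.01 mm/px): at 0.005 mm/px errors stay ≈ 1%; at
0.01 mm/px mid-to-high compliances still recover to ≈ 1–2% but
C* = 0.3 degrades to ≈ 30–45% — at that scale the excursion is simply
below the estimator's quantisation floor.  Frame stacks default to
uint8 with a 2200×40 px geometry (the ten stations need width, not the
full field of view).

What the fixtures do *not* emulate: illumination gradients, lens
distortion, out-of-plane motion, specular highlights, wall-thickness
change under strain, or real silicone nonlinearity.  Passing the
recovery tests therefore demonstrates the correctness of the
measurement chain under its stated image model, not robustness to real
microscope footage.

## Waveform analytics

Acquisition decimates simulator-resolution traces to the sensor rates
(pressure 40 Hz, flow 200 Hz) by stride when rates divide, otherwise by
linear interpolation; Gaussian sensor noise (defaults SD 0.5 mmHg and
1 mL/min — the bench reports spreads, not a noise model) is applied
exactly once, at acquisition.  All analysis runs on 3-point
moving-average filtered traces; the edge rule averages the available
neighbours (2-point at the ends), preserving length.

Cycle boundaries anchor at pressure minima (the controller is
pressure-referenced), found with a minimum spacing of 75% of the
nominal period and a prominence of 10% of the trace range.  On
coronary-like runs the detected minima sit up to ~0.1 s *early*: the
diastolic pressure tail is nearly flat, so 0.5 mmHg of sensor noise at
40 Hz moves the argmin.  Checks that place events inside the 0.35 s
systolic window therefore carry a 0.1 s alignment allowance.

The counter-phase index resamples flow onto the pressure clock,
mean-removes both, and reports the cross-correlation peak lag
restricted to (−T/2, T/2] (positive lag = flow trails pressure)
together with the diastolic flow fraction — the share of per-cycle
volume delivered outside the systolic window, >0.5 meaning
diastolic-dominant perfusion (the twin's coronary runs give ≈ 0.75).

Long-term stability is emulated as independent seeded runs labelled by
timepoint (no drift model: the bench found none).  Welch's
heteroscedastic one-way ANOVA (via pingouin, cross-checked against
Welch's t with F = t² for two groups) compares each of the five
metrics (P_min, P_max, ΔP, Q_mean, ΔQ) across timepoints, with the
per-cycle values within a run as the group sample — the convention
matching a per-timepoint mean ± SD summary table.

## Known limitations

* Lumped, zero-dimensional hydraulics: no wave propagation, no
  fluid–structure interaction, no actuator dynamics (slew, hysteresis).
* The circuit element values and the valve transfer law are this
  package's calibration, so absolute closures and time constants are
  illustrative; the controller's job is precisely to make the pressure
  outcomes insensitive to them.
* The linear phantom cannot reproduce the across-regime compliance
  trend of real silicone (see above).
* Compliance recovery at the default 0.002 mm/px holds under the
  stated synthetic image model; bench-camera scales near 0.01 mm/px
  resolve only compliances whose pulse excursion exceeds ≈ 1 px.
* Temperature is a configuration constant (it enters only through the
  viscosity model); the heat exchanger is not modelled.
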