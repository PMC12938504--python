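"""Mechanical and fluid-property models of the test article.

The test article is a silicone tubular phantom (3.2 mm inner diameter,
0.4 mm wall) standing in for a small-caliber vascular graft.  Its
pressure--diameter behaviour is modelled as a linearised distension law:
over a single 40 mmHg pulse window the bench data are near-linear, and the
two-point dynamic-compliance definition used throughout this package only
ever samples the law at two pressures.  The working fluid of the
coronary-like configuration is a glycerol--water mixture whose dynamic
viscosity is computed with the Cheng (2008) exponential-mixing correlation.
Wall shear stress is estimated with the Poiseuille formula for fully
developed laminar tube flow.

Units: pressures in mmHg, diameters in mm, flow in mL/min, viscosity in
mPa*s, wall shear stress in Pa.  All unit conversions happen inside the
functions; callers never pass SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "PhantomSpec",
    "FluidSpec",
    "diameter_at_pressure",
    "glycerol_viscosity",
    "poiseuille_wss",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and linearised mechanics of the tubular phantom.

    ``distension_coeff`` is the fractional inner-diameter change per mmHg
    around ``reference_pressure``:

        D_inner(p) = inner_diameter_ref * (1 + distension_coeff * (p - reference_pressure))

    The default distension is calibrated from the bench normotensive
    anchors (3.227 mm at 79.67 mmHg, 3.237 mm at 120.72 mmHg).
    """

    inner_diameter_ref: float = 3.227
    wall_thickness: float = 0.4
    length: float = 50.0
    distension_coeff: float = 7.548973e-05
    reference_pressure: float = 79.67

    def __post_init__(self) -> None:
        if self.inner_diameter_ref <= 0:
            raise ConfigurationError("inner_diameter_ref must be > 0")
        if self.wall_thickness <= 0:
            raise ConfigurationError("wall_thickness must be > 0")
        if self.distension_coeff < 0:
            raise ConfigurationError("distension_coeff must be >= 0")

    @classmethod
    def from_anchors(
        cls,
        d1: float,
        p1: float,
        d2: float,
        p2: float,
        wall_thickness: float = 0.4,
        length: float = 50.0,
    ) -> "PhantomSpec":
        """Build a spec that reproduces two (pressure, inner diameter) anchors exactly."""
        if p2 == p1:
            raise ConfigurationError("anchor pressures must differ")
        alpha = (d2 - d1) / (d1 * (p2 - p1))
        return cls(
            inner_diameter_ref=d1,
            wall_thickness=wall_thickness,
            length=length,
            distension_coeff=alpha,
            reference_pressure=p1,
        )

    @classmethod
    def from_compliance(
        cls,
        compliance: float,
        p_min: float,
        inner_diameter: float = 3.2,
        wall_thickness: float = 0.4,
        length: float = 50.0,
    ) -> "PhantomSpec":
        """Build a spec with a prescribed dynamic radial compliance.

        ``compliance`` is in % 10^-2 mmHg^-1 as in the two-point definition
        C = ((D(p_max) - D(p_min)) / D(p_min)) / (p_max - p_min) * 1e4.
        With the reference pressure anchored at ``p_min`` the round trip is
        exact for every p_max.
        """
        return cls(
            inner_diameter_ref=inner_diameter,
            wall_thickness=wall_thickness,
            length=length,
            distension_coeff=compliance / 1.0e4,
            reference_pressure=p_min,
        )


@dataclass(frozen=True)
class FluidSpec:
    """Glycerol--water working fluid.

    The coronary-like runs use distilled water supplemented with 50% (w/w)
    glycerol at 37 C to mimic blood viscosity.
    """

    glycerol_mass_fraction: float = 0.50
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.glycerol_mass_fraction <= 1.0:
            raise ConfigurationError("glycerol_mass_fraction must be in [0, 1]")

    @property
    def dynamic_viscosity(self) -> float:
        """Dynamic viscosity in mPa*s via the Cheng correlation."""
        return glycerol_viscosity(self.glycerol_mass_fraction, self.temperature)


def diameter_at_pressure(spec: PhantomSpec, p):
    """Inner and outer diameter (mm) of the phantom at luminal pressure ``p`` (mmHg).

    Quasi-static: the diameter follows pressure instantaneously, and the
    wall thickness is treated as constant under pressurisation, so
    ``outer = inner + 2 * wall_thickness``.

    Accepts scalars or arrays; raises if any resulting inner diameter
    would be non-positive.
    """
    p = np.asarray(p, dtype=float)
    inner = spec.inner_diameter_ref * (
        1.0 + spec.distension_coeff * (p - spec.reference_pressure)
    )
    if np.any(inner <= 0):
        raise ValueError("pressure drives inner diameter <= 0")
    outer = inner + 2.0 * spec.wall_thickness
    if inner.ndim == 0:
        return float(inner), float(outer)
    return inner, outer


#: Validity range of the Cheng (2008) glycerol-water correlation, deg C.
_CHENG_T_RANGE = (0.0, 100.0)


def glycerol_viscosity(mass_fraction: float, temperature_C: float) -> float:
    """Dynamic viscosity (mPa*s) of a glycerol--water mixture.

    Uses the Cheng (2008) correlation: the mixture viscosity is a
    weighted geometric mean of the pure-component viscosities,

        mu = mu_water^alpha * mu_glycerol^(1 - alpha),

    with a composition- and temperature-dependent weight alpha.  Valid for
    temperatures between 0 and 100 C and the full 0..1 mass-fraction range.
    At 50% (w/w) and 37 C it gives ~3.4 mPa*s, matching the working fluid
    of the coronary-like configuration.
    """
    if not 0.0 <= mass_fraction <= 1.0:
        raise ValueError("mass_fraction must be in [0, 1]")
    t_lo, t_hi = _CHENG_T_RANGE
    if not t_lo <= temperature_C <= t_hi:
        raise ValueError(
            f"temperature {temperature_C} C outside correlation validity "
            f"range [{t_lo}, {t_hi}] C"
        )
    T = temperature_C
    cm = mass_fraction
    a = 0.705 - 0.0017 * T
    b = (4.9 + 0.036 * T) * a**2.5
    alpha = 1.0 - cm + (a * b * cm * (1.0 - cm)) / (a * cm + b * (1.0 - cm))
    mu_water = 1.790 * math.exp((-1230.0 - T) * T / (36100.0 + 360.0 * T))
    mu_glycerol = 12100.0 * math.exp((-1233.0 + T) * T / (9900.0 + 70.0 * T))
    return mu_water**alpha * mu_glycerol ** (1.0 - alpha)


def poiseuille_wss(flow: float, viscosity: float, lumen_diameter: float) -> float:
    """Mean wall shear stress (Pa) for Poiseuille flow in a straight tube.

    tau = 4 mu Q / (pi r^3), with ``flow`` in mL/min, ``viscosity`` in
    mPa*s, and ``lumen_diameter`` in mm.  At the coronary-like operating
    point (188.42 mL/min, 3.5 mPa*s, 3.2 mm lumen) this evaluates to
    ~3.4 Pa.
    """
    if lumen_diameter <= 0:
        raise ValueError("lumen_diameter must be > 0")
    if viscosity <= 0:
        raise ValueError("viscosity must be > 0")
    if flow < 0:
        raise ValueError("flow must be >= 0")
    q_si = flow * 1e-6 / 60.0  # mL/min -> m^3/s
    mu_si = viscosity * 1e-3  # mPa*s -> Pa*s
    r_si = lumen_diameter * 1e-3 / 2.0  # mm -> m
    return 4.0 * mu_si * q_si / (math.pi * r_si**3)
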