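"""Shear environment of a stirred, unbaffled, paddle-impeller bioreactor.

Given vessel geometry, fluid properties and an agitation rate, this module
computes the quantities that characterise the hydrodynamic stress a
suspended cell experiences:

* impeller Reynolds number ``Re = N d^2 / nu``
* Nagata power number for unbaffled vessels (transitional regime)
* impeller power draw ``P = N_p N^3 d^5 rho``
* specific energy dissipation rate ``epsilon = P / (V_L rho)``
* maximum shear stress ``tau_max = 5.33 rho (epsilon nu)^(1/2)``
* integrated shear factor ``ISF = 2 pi N d / (D - d)``
* Kolmogorov eddy length ``lambda_K = (nu^3 / epsilon)^(1/4)``

and compares ``tau_max`` against a literature threshold for hematopoietic
cell proliferation (0.092 Pa by default).

All formulas work in SI units; agitation speed is converted from rpm to
rev/s once, at :class:`AgitationCondition` construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "InvalidInputError",
    "InvalidGeometryError",
    "VesselGeometry",
    "FluidProperties",
    "AgitationCondition",
    "HydrodynamicReport",
    "SHEAR_THRESHOLD_PA",
    "DEFAULT_BLADE_RATIO",
    "reynolds_number",
    "nagata_power_number",
    "impeller_power",
    "energy_dissipation",
    "max_shear_stress",
    "integrated_shear_factor",
    "kolmogorov_length",
    "shear_threshold_check",
    "hydrodynamic_report",
]


class InvalidInputError(ValueError):
    """Raised when a physical quantity is out of its admissible range."""


class InvalidGeometryError(InvalidInputError):
    """Raised when vessel/impeller dimensions are mutually inconsistent."""


#: Literature threshold shear stress for hematopoietic stem cell
#: proliferation and function (Pa).
SHEAR_THRESHOLD_PA = 0.092

#: Default blade-height to vessel-diameter ratio for a flat-blade paddle.
#: Calibrated so the Nagata power number reproduces the reference pair
#: (0.78, 0.69) at Re = 868 / 1764 within +/-0.01 (verified by a brute-force
#: sweep of b/D in [0.03, 0.15]).
DEFAULT_BLADE_RATIO = 0.06


def _require_finite_positive(name: str, value: float, *, strict: bool = True) -> None:
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    if strict and value <= 0:
        raise InvalidInputError(f"{name} must be > 0, got {value!r}")
    if not strict and value < 0:
        raise InvalidInputError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class VesselGeometry:
    """Cylindrical vessel with a centred flat-blade paddle impeller.

    Parameters
    ----------
    vessel_diameter:
        Inner vessel diameter ``D`` (m).
    impeller_diameter:
        Impeller diameter ``d`` (m); must satisfy ``0 < d < D``.
    blade_height:
        Paddle blade height ``b`` (m).
    liquid_height:
        Medium height ``H`` (m).
    working_volume:
        Liquid working volume ``V_L`` (m^3). Must be cylindrically
        consistent with ``D`` and ``H`` to within 5 %.
    """

    vessel_diameter: float
    impeller_diameter: float
    blade_height: float
    liquid_height: float
    working_volume: float

    def __post_init__(self) -> None:
        _require_finite_positive("vessel_diameter", self.vessel_diameter)
        _require_finite_positive("impeller_diameter", self.impeller_diameter)
        _require_finite_positive("blade_height", self.blade_height)
        _require_finite_positive("liquid_height", self.liquid_height)
        _require_finite_positive("working_volume", self.working_volume)
        if self.impeller_diameter >= self.vessel_diameter:
            raise InvalidGeometryError(
                "impeller diameter must be smaller than vessel diameter "
                f"(d={self.impeller_diameter}, D={self.vessel_diameter})"
            )
        cyl = math.pi * (self.vessel_diameter / 2.0) ** 2 * self.liquid_height
        if abs(self.working_volume - cyl) / self.working_volume > 0.05:
            raise InvalidGeometryError(
                f"working volume {self.working_volume:.3e} m^3 deviates more "
                f"than 5 % from the cylindrical volume {cyl:.3e} m^3 implied "
                "by D and H"
            )

    @property
    def aspect_ratio(self) -> float:
        """Medium height to vessel diameter, ``H / D``."""
        return self.liquid_height / self.vessel_diameter

    @property
    def d_over_D(self) -> float:
        """Impeller to vessel diameter ratio."""
        return self.impeller_diameter / self.vessel_diameter

    @property
    def b_over_D(self) -> float:
        """Blade height to vessel diameter ratio."""
        return self.blade_height / self.vessel_diameter


@dataclass(frozen=True)
class FluidProperties:
    """Density and viscosity of the culture medium.

    Water properties (``rho`` = 1000 kg/m^3, ``nu`` = 1e-6 m^2/s) are an
    adequate stand-in for typical basal media and are the defaults of
    :meth:`water`.
    """

    density: float  # kg/m^3
    dynamic_viscosity: float  # Pa s

    def __post_init__(self) -> None:
        _require_finite_positive("density", self.density)
        _require_finite_positive("dynamic_viscosity", self.dynamic_viscosity)

    @property
    def kinematic_viscosity(self) -> float:
        """``nu = mu_f / rho`` (m^2/s)."""
        return self.dynamic_viscosity / self.density

    @classmethod
    def from_kinematic(cls, density: float, kinematic_viscosity: float) -> "FluidProperties":
        _require_finite_positive("density", density)
        _require_finite_positive("kinematic_viscosity", kinematic_viscosity)
        return cls(density=density, dynamic_viscosity=kinematic_viscosity * density)

    @classmethod
    def water(cls) -> "FluidProperties":
        """Water at ambient conditions: rho = 1000 kg/m^3, nu = 1e-6 m^2/s."""
        return cls.from_kinematic(1000.0, 1.0e-6)


@dataclass(frozen=True)
class AgitationCondition:
    """Impeller agitation rate, stored in rpm, exposed in rev/s."""

    speed_rpm: float

    def __post_init__(self) -> None:
        _require_finite_positive("speed_rpm", self.speed_rpm, strict=False)

    @property
    def speed_rps(self) -> float:
        """Rotational speed ``N`` in rev/s; all formulas use this."""
        return self.speed_rpm / 60.0

    @classmethod
    def from_rps(cls, speed_rps: float) -> "AgitationCondition":
        return cls(speed_rpm=speed_rps * 60.0)


@dataclass(frozen=True)
class HydrodynamicReport:
    """One column of a hydrodynamic-parameter table for a single agitation rate.

    ``kla`` is a user-supplied volumetric oxygen transfer coefficient (1/h);
    it is never computed here, only carried through when provided.
    """

    speed_rpm: float
    reynolds: float
    power_number: float
    power: float  # W
    epsilon: float  # W/kg
    tau_max: float  # Pa
    isf: float  # 1/s
    kolmogorov_length: float  # m
    threshold: float = SHEAR_THRESHOLD_PA  # Pa
    kla: Optional[float] = None  # 1/h, pass-through only
    shear_exceeds_threshold: bool = field(init=False)

    def __post_init__(self) -> None:
        for name in ("reynolds", "power_number", "power", "epsilon",
                     "tau_max", "isf", "kolmogorov_length", "threshold"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")
        object.__setattr__(self, "shear_exceeds_threshold", self.tau_max > self.threshold)

    @property
    def shear_margin(self) -> float:
        """``tau_max - threshold`` (Pa); positive means the threshold is exceeded."""
        return self.tau_max - self.threshold


# ---------------------------------------------------------------------------
# Elementary operations, in the order the calculation chain runs
# ---------------------------------------------------------------------------

def reynolds_number(
    geometry: VesselGeometry,
    fluid: FluidProperties,
    agitation: AgitationCondition,
) -> float:
    """Impeller Reynolds number ``Re = N d^2 / nu``.

    Linear in the agitation speed; zero at rest.
    """
    N = agitation.speed_rps
    return N * geometry.impeller_diameter**2 / fluid.kinematic_viscosity


def nagata_power_number(geometry: VesselGeometry, reynolds: float) -> float:
    """Power number from Nagata's correlation for unbaffled vessels.

    ``N_p = A/Re + B * [(1e3 + 1.2 Re^0.66) / (1e3 + 3.2 Re^0.66)]^p`` with

    * ``A = 14 + (b/D) [670 (d/D - 0.6)^2 + 185]``
    * ``B = 10^(1.3 - 4 (b/D - 0.5)^2 - 1.14 (d/D))``
    * ``p = 1.1 + 4 (b/D) - 2.5 (d/D - 0.5)^2 - 7 (b/D)^4``

    Valid for a flat-blade paddle in a transitional/turbulent unbaffled
    tank; ``d/D`` and ``b/D`` must lie in (0, 1).
    """
    if not math.isfinite(reynolds) or reynolds <= 0:
        raise InvalidInputError(f"Reynolds number must be > 0, got {reynolds!r}")
    dD = geometry.d_over_D
    bD = geometry.b_over_D
    if not 0 < dD < 1 or not 0 < bD < 1:
        raise InvalidGeometryError(
            f"geometry ratios outside correlation range: d/D={dD}, b/D={bD}"
        )
    A = 14.0 + bD * (670.0 * (dD - 0.6) ** 2 + 185.0)
    B = 10.0 ** (1.3 - 4.0 * (bD - 0.5) ** 2 - 1.14 * dD)
    p = 1.1 + 4.0 * bD - 2.5 * (dD - 0.5) ** 2 - 7.0 * bD**4
    x = reynolds**0.66
    return A / reynolds + B * ((1.0e3 + 1.2 * x) / (1.0e3 + 3.2 * x)) ** p


def impeller_power(
    power_number: float,
    agitation: AgitationCondition,
    geometry: VesselGeometry,
    fluid: FluidProperties,
) -> float:
    """Impeller power draw ``P = N_p N^3 d^5 rho`` (W)."""
    _require_finite_positive("power_number", power_number, strict=False)
    N = agitation.speed_rps
    return power_number * N**3 * geometry.impeller_diameter**5 * fluid.density


def energy_dissipation(power: float, geometry: VesselGeometry, fluid: FluidProperties) -> float:
    """Specific energy dissipation rate ``epsilon = P / (V_L rho)`` (W/kg)."""
    _require_finite_positive("power", power, strict=False)
    return power / (geometry.working_volume * fluid.density)


def max_shear_stress(epsilon: float, fluid: FluidProperties) -> float:
    """Maximum shear stress on a suspended cell, ``tau_max = 5.33 rho (epsilon nu)^(1/2)`` (Pa)."""
    _require_finite_positive("epsilon", epsilon, strict=False)
    return 5.33 * fluid.density * math.sqrt(epsilon * fluid.kinematic_viscosity)


def integrated_shear_factor(geometry: VesselGeometry, agitation: AgitationCondition) -> float:
    """Integrated shear factor ``ISF = 2 pi N d / (D - d)`` (1/s).

    An averaged measure of the shear in the gap between impeller tip and
    vessel wall; requires ``D > d`` (enforced at geometry construction).
    """
    N = agitation.speed_rps
    return (
        2.0 * math.pi * N * geometry.impeller_diameter
        / (geometry.vessel_diameter - geometry.impeller_diameter)
    )


def kolmogorov_length(epsilon: float, fluid: FluidProperties) -> float:
    """Kolmogorov eddy microscale ``lambda_K = (nu^3 / epsilon)^(1/4)`` (m).

    Cells much smaller than ``lambda_K`` largely follow the local flow
    rather than being strained by individual eddies.
    """
    if not math.isfinite(epsilon) or epsilon <= 0:
        raise InvalidInputError(f"epsilon must be > 0, got {epsilon!r}")
    return (fluid.kinematic_viscosity**3 / epsilon) ** 0.25


def shear_threshold_check(
    tau_max: float, threshold: float = SHEAR_THRESHOLD_PA
) -> tuple[bool, float]:
    """Compare ``tau_max`` against a threshold (strict inequality).

    Returns ``(tau_max > threshold, tau_max - threshold)``.
    """
    _require_finite_positive("tau_max", tau_max, strict=False)
    _require_finite_positive("threshold", threshold, strict=False)
    return tau_max > threshold, tau_max - threshold


def hydrodynamic_report(
    geometry: VesselGeometry,
    fluid: FluidProperties,
    agitation: AgitationCondition,
    kla: Optional[float] = None,
    threshold: float = SHEAR_THRESHOLD_PA,
) -> HydrodynamicReport:
    """Chain all hydrodynamic operations into a single self-consistent report."""
    re = reynolds_number(geometry, fluid, agitation)
    np_ = nagata_power_number(geometry, re)
    p = impeller_power(np_, agitation, geometry, fluid)
    eps = energy_dissipation(p, geometry, fluid)
    return HydrodynamicReport(
        speed_rpm=agitation.speed_rpm,
        reynolds=re,
        power_number=np_,
        power=p,
        epsilon=eps,
        tau_max=max_shear_stress(eps, fluid),
        isf=integrated_shear_factor(geometry, agitation),
        kolmogorov_length=kolmogorov_length(eps, fluid),
        threshold=threshold,
        kla=kla,
    )
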