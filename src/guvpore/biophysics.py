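"""Membrane electro-mechanics of pulsed giant unilamellar vesicles.

This module implements the physical model used to interpret vesicle
electroporation movies:

* the membrane charging time ``tau`` of a spherical vesicle and the induced
  transmembrane voltage ``psi_m = 1.5 R E (1 - exp(-t/tau))``,
* the electrical membrane tension ``sigma_el ~ 0.5 C_m psi_m**2``,
* the force balance between the electric tether-pulling force
  ``F_el = 2 pi sqrt(2 k_c sigma_el)`` and the viscous drag
  ``F_v = 2 pi eta_eff V_t`` that decides whether lipid can be expelled
  (fluid-phase membranes) or not (gel-phase membranes, whose surface
  viscosity is roughly six orders of magnitude larger),
* the single-pore efflux ``Q = 2 sigma r**3 / (3 eta_0 R)`` and its exact
  inversion, which converts a measured volumetric efflux into a pore radius,
* the efflux inferred from the projected-area loss of a spherical vesicle,
  ``Q = -sqrt(4 A / pi) dA/dt``,
* an adiabatic Joule-heating bound ``dT = lambda E**2 dt / (rho c_p)``.

All functions take and return SI units (m, s, V/m, F/m^2, N/m, Pa.s, m^3/s).
Helper converters are provided for the lab units in which the constants are
usually quoted (uS/cm, uF/cm^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MediumParams",
    "MembraneParams",
    "PulseField",
    "PoreEstimate",
    "uS_per_cm_to_S_per_m",
    "uF_per_cm2_to_F_per_m2",
    "fluid_membrane",
    "gel_membrane",
    "default_medium",
    "charging_time",
    "transmembrane_voltage",
    "electrical_tension",
    "tether_force",
    "viscous_force",
    "max_tubule_speed",
    "pore_efflux",
    "pore_radius_from_efflux",
    "efflux_from_area_rate",
    "joule_heating",
]


def uS_per_cm_to_S_per_m(value: float) -> float:
    """Convert a conductivity from uS/cm to S/m."""
    return value * 1e-4


def uF_per_cm2_to_F_per_m2(value: float) -> float:
    """Convert an areal capacitance from uF/cm^2 to F/m^2."""
    return value * 1e-2


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class MediumParams:
    """Properties of the aqueous media inside and outside the vesicle.

    Attributes
    ----------
    lambda_ext, lambda_int:
        External / internal electrical conductivity, S/m. Defaults are the
        sucrose/glucose solutions of the reference experiment
        (4.5 and 6 uS/cm).
    eta0:
        Viscosity of the internal liquid, Pa.s (water at room temperature).
    vol_heat_capacity:
        Volumetric heat capacity rho*c_p, J/(m^3 K) (dilute aqueous solution).
    """

    lambda_ext: float = 4.5e-4
    lambda_int: float = 6.0e-4
    eta0: float = 1.0e-3
    vol_heat_capacity: float = 4.18e6

    def __post_init__(self):
        _require_positive(
            lambda_ext=self.lambda_ext,
            lambda_int=self.lambda_int,
            eta0=self.eta0,
            vol_heat_capacity=self.vol_heat_capacity,
        )


@dataclass(frozen=True)
class MembraneParams:
    """Mechanical and electrical constants of the lipid bilayer.

    Attributes
    ----------
    c_m:
        Areal membrane capacitance, F/m^2.
    k_c:
        Bending elasticity modulus, J.
    eta_eff:
        Effective surface viscosity (membrane viscosity plus intermonolayer
        slip), N.s/m. Gel-phase membranes are ~1e6-fold more viscous than
        fluid-phase ones.
    sigma_mem:
        Membrane surface tension driving pore efflux, N/m. No measured value
        is available for the reference experiment; the default is an
        order-of-magnitude placeholder and should be set explicitly for
        quantitative pore-size claims.
    """

    c_m: float = 5.0e-3
    k_c: float = 1.0e-19
    eta_eff: float = 5.0e-9
    sigma_mem: float = 1.0e-3

    def __post_init__(self):
        _require_positive(
            c_m=self.c_m, k_c=self.k_c, eta_eff=self.eta_eff, sigma_mem=self.sigma_mem
        )


def fluid_membrane(**overrides) -> MembraneParams:
    """Defaults for a fluid-phase (DPhPC-like) membrane: C_m = 0.5 uF/cm^2."""
    params = dict(c_m=uF_per_cm2_to_F_per_m2(0.5), k_c=1.0e-19, eta_eff=5.0e-9, sigma_mem=1.0e-3)
    params.update(overrides)
    return MembraneParams(**params)


def gel_membrane(**overrides) -> MembraneParams:
    """Defaults for a gel-phase (DPPC-like) membrane: C_m = 0.45 uF/cm^2,
    surface viscosity six orders of magnitude above the fluid value."""
    params = dict(c_m=uF_per_cm2_to_F_per_m2(0.45), k_c=1.0e-19, eta_eff=5.0e-3, sigma_mem=1.0e-3)
    params.update(overrides)
    return MembraneParams(**params)


def default_medium() -> MediumParams:
    """Sucrose-inside / glucose-outside medium of the reference experiment."""
    return MediumParams()


@dataclass(frozen=True)
class PulseField:
    """One applied DC pulse as seen by a vesicle of radius ``radius``.

    Attributes: ``e_field`` V/m, ``duration`` s, ``radius`` m.
    """

    e_field: float
    duration: float
    radius: float

    def __post_init__(self):
        _require_nonnegative(e_field=self.e_field, duration=self.duration)
        _require_positive(radius=self.radius)


@dataclass(frozen=True)
class PoreEstimate:
    """A single-pore interpretation of a measured efflux.

    ``efflux`` (m^3/s) and ``radius`` (m) are tied together by the
    single-pore law Q = 2 sigma r^3 / (3 eta0 R). The single-pore assumption
    is carried explicitly in ``assumptions``.
    """

    efflux: float
    radius: float
    assumptions: str = "single-pore"

    def __post_init__(self):
        _require_nonnegative(efflux=self.efflux, radius=self.radius)


def charging_time(
    radius: float,
    membrane: MembraneParams,
    medium: MediumParams,
    variant: str = "halved_external",
) -> float:
    """Characteristic membrane charging time of a spherical vesicle, s.

    Two variants are provided:

    * ``"halved_external"`` (default): tau = R C_m (1/lambda_i + 1/(2 lambda_e)),
      the spherical-shell charging time. With the reference constants
      (R = 20 um, C_m = 0.45 uF/cm^2, lambda_e = 4.5 uS/cm,
      lambda_i = 6 uS/cm) it gives 250 us for a gel-phase vesicle and about
      300 us for a fluid-phase one, the reference values for these
      conditions.
    * ``"simplified"``: tau = R C_m (1/lambda_e + 1/lambda_i), a common
      simplification that neglects the spherical-shell factor; the same
      inputs give 350 us.
    """
    _require_positive(radius=radius)
    if variant == "halved_external":
        inv = 1.0 / medium.lambda_int + 1.0 / (2.0 * medium.lambda_ext)
    elif variant == "simplified":
        inv = 1.0 / medium.lambda_ext + 1.0 / medium.lambda_int
    else:
        raise ValueError(f"unknown charging-time variant {variant!r}")
    return radius * membrane.c_m * inv


def transmembrane_voltage(pulse: PulseField, tau: float) -> float:
    """Maximum (pole) transmembrane voltage, V: 1.5 R E (1 - exp(-t/tau))."""
    _require_positive(tau=tau)
    return 1.5 * pulse.radius * pulse.e_field * (1.0 - math.exp(-pulse.duration / tau))


def electrical_tension(c_m: float, psi_m: float) -> float:
    """Electric membrane tension sigma_el ~ 0.5 C_m psi_m^2, N/m."""
    _require_positive(c_m=c_m)
    return 0.5 * c_m * psi_m**2


def tether_force(k_c: float, sigma_el: float) -> float:
    """Electric tubule-pulling (tether) force F_el = 2 pi sqrt(2 k_c sigma_el), N."""
    _require_nonnegative(k_c=k_c, sigma_el=sigma_el)
    return 2.0 * math.pi * math.sqrt(2.0 * k_c * sigma_el)


def viscous_force(eta_eff: float, v_t: float) -> float:
    """Viscous force opposing tubule elongation at speed v_t: 2 pi eta_eff v_t, N."""
    _require_nonnegative(eta_eff=eta_eff, v_t=v_t)
    return 2.0 * math.pi * eta_eff * v_t


def max_tubule_speed(k_c: float, sigma_el: float, eta_eff: float) -> float:
    """Tubule elongation speed at which the viscous drag balances F_el, m/s.

    V_t* = F_el / (2 pi eta_eff) = sqrt(2 k_c sigma_el) / eta_eff. A gel-phase
    membrane with eta_eff a factor 1e6 above the fluid value therefore reaches
    a 1e6-fold smaller speed at the same electrical tension, which is why gel
    vesicles lose no lipid on the pulse time scale.
    """
    _require_positive(eta_eff=eta_eff)
    _require_nonnegative(k_c=k_c, sigma_el=sigma_el)
    return tether_force(k_c, sigma_el) / (2.0 * math.pi * eta_eff)


def pore_efflux(r: float, sigma_mem: float, eta0: float, radius: float) -> float:
    """Volumetric efflux through a single pore of radius r, m^3/s.

    Q = 2 sigma r^3 / (3 eta0 R), where sigma is the membrane tension driving
    the outflow, eta0 the liquid viscosity and R the vesicle radius.
    """
    _require_positive(sigma_mem=sigma_mem, eta0=eta0, radius=radius)
    _require_nonnegative(r=r)
    return 2.0 * sigma_mem * r**3 / (3.0 * eta0 * radius)


def pore_radius_from_efflux(q: float, sigma_mem: float, eta0: float, radius: float) -> float:
    """Exact inverse of :func:`pore_efflux`: r = (3 eta0 R Q / (2 sigma))^(1/3)."""
    _require_positive(sigma_mem=sigma_mem, eta0=eta0, radius=radius)
    _require_nonnegative(q=q)
    return (3.0 * eta0 * radius * q / (2.0 * sigma_mem)) ** (1.0 / 3.0)


def efflux_from_area_rate(area: float, area_rate: float) -> float:
    """Efflux from the projected-area loss of a spherical vesicle, m^3/s.

    With A = pi R^2 the projected disc area, Q = -dV/dt = -sqrt(4 A / pi) dA/dt.
    Positive for a shrinking vesicle.
    """
    _require_positive(area=area)
    return -math.sqrt(4.0 * area / math.pi) * area_rate


def joule_heating(
    conductivity: float, e_field: float, duration: float, vol_heat_capacity: float
) -> float:
    """Adiabatic upper bound on the temperature rise of one pulse, K.

    dT = lambda E^2 dt / (rho c_p); dissipated power density lambda E^2 with
    no heat transport during the (sub-millisecond) pulse.
    """
    _require_positive(conductivity=conductivity, duration=duration, vol_heat_capacity=vol_heat_capacity)
    _require_nonnegative(e_field=e_field)
    return conductivity * e_field**2 * duration / vol_heat_capacity
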