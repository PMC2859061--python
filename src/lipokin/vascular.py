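"""Axial mass transfer of liposomes in a blood vessel.

Blood is treated as a constant-viscosity, incompressible Newtonian fluid
in steady, fully developed laminar flow through a straight vessel of
radius ``Rv`` (Hagen-Poiseuille):

    v(r) = 2 U (1 - (r/Rv)^2),      U = Rv^2 (-dP/dz) / (8 mu)

Liposomes leave the bloodstream through the wall against three film
resistances in series -- blood side ``kc``, vessel wall ``km``, tissue
``kt`` -- giving an overall coefficient ``1/K = 1/kc + 1/km + 1/kt`` and
wall flux ``Nr = K (Cb - Ct)`` toward a tissue boundary concentration
``Ct`` (default 0: perfect sink).  Neglecting axial diffusion (large
Peclet number) the cross-section-averaged balance

    pi Rv^2 U dCb/dz = -2 pi Rv K (Cb - Ct)

integrates to an exponential axial decay of the bulk concentration:

    Cb(z) = Ct + (Co - Ct) exp(-2 K z / (Rv U)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "VesselSpec",
    "TransportCoefficients",
    "velocity_profile",
    "mean_velocity_from_pressure",
    "overall_coefficient",
    "bulk_concentration",
    "wall_flux",
    "delivered_fraction",
    "axial_profile",
]


@dataclass(frozen=True)
class VesselSpec:
    """Vessel geometry and hemodynamics.

    Exactly one of ``pressure_gradient`` (Pa/m, negative for forward
    flow) or ``mean_velocity`` (m/s) is supplied; the other is derived
    from the Poiseuille relation.  Reverse flow (adverse gradient) is
    rejected unless ``allow_reverse`` is set, in which case the mean
    velocity is negative and the profile sign follows it.
    """

    radius: float
    viscosity: float
    length: float
    pressure_gradient: float | None = None
    mean_velocity: float | None = None
    allow_reverse: bool = False

    def __post_init__(self) -> None:
        problems = []
        if not self.radius > 0:
            problems.append(f"radius must be > 0, got {self.radius!r}")
        if not self.viscosity > 0:
            problems.append(f"viscosity must be > 0, got {self.viscosity!r}")
        if not self.length > 0:
            problems.append(f"length must be > 0, got {self.length!r}")
        if (self.pressure_gradient is None) == (self.mean_velocity is None):
            problems.append(
                "exactly one of pressure_gradient or mean_velocity must be supplied"
            )
        if problems:
            raise ValidationError("; ".join(problems))
        if self.mean_velocity is not None and self.mean_velocity < 0 and not self.allow_reverse:
            raise ValidationError(
                "negative mean_velocity requires allow_reverse=True"
            )
        if (
            self.pressure_gradient is not None
            and self.pressure_gradient > 0
            and not self.allow_reverse
        ):
            raise ValidationError(
                "adverse (positive) pressure gradient gives reverse flow; "
                "set allow_reverse=True to permit it"
            )

    @property
    def U(self) -> float:
        """Mean axial velocity (m/s), derived if a gradient was given."""
        if self.mean_velocity is not None:
            return self.mean_velocity
        return mean_velocity_from_pressure(self)


@dataclass(frozen=True)
class TransportCoefficients:
    """Serial mass-transfer coefficients and tissue boundary concentration.

    ``kc``: blood-side film, ``km``: vessel wall, ``kt``: tissue space,
    all in m/s; ``ct``: liposome concentration in the tissue at the outer
    wall surface (same units as the bulk concentration, default 0).
    """

    kc: float
    km: float
    kt: float
    ct: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("kc", "km", "kt"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                problems.append(f"{name} must be positive and finite, got {v!r}")
        if self.ct < 0:
            problems.append(f"ct must be >= 0, got {self.ct!r}")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def overall(self) -> float:
        return overall_coefficient(self)


def velocity_profile(vessel: VesselSpec, r) -> np.ndarray | float:
    """Parabolic axial velocity 2U(1 - (r/Rv)^2) at radius ``r``."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr < 0) or np.any(r_arr > vessel.radius):
        raise DomainError(f"r must lie in [0, Rv={vessel.radius:g}]")
    v = 2.0 * vessel.U * (1.0 - (r_arr / vessel.radius) ** 2)
    return float(v[0]) if np.isscalar(r) else v


def mean_velocity_from_pressure(vessel: VesselSpec) -> float:
    """Poiseuille mean velocity U = Rv^2 (-dP/dz) / (8 mu)."""
    if vessel.pressure_gradient is None:
        raise ValidationError("vessel was specified by mean velocity, not gradient")
    return vessel.radius**2 * (-vessel.pressure_gradient) / (8.0 * vessel.viscosity)


def overall_coefficient(coeffs: TransportCoefficients) -> float:
    """Overall transfer coefficient: 1/K = 1/kc + 1/km + 1/kt."""
    return 1.0 / (1.0 / coeffs.kc + 1.0 / coeffs.km + 1.0 / coeffs.kt)


def _decay_rate(vessel: VesselSpec, coeffs: TransportCoefficients) -> float:
    u = vessel.U
    if u == 0:
        raise ValidationError(
            "mean velocity is zero: the convective model (large Peclet "
            "number) does not apply without flow"
        )
    return 2.0 * overall_coefficient(coeffs) / (vessel.radius * u)


def bulk_concentration(
    vessel: VesselSpec,
    coeffs: TransportCoefficients,
    c0: float,
    z,
) -> np.ndarray | float:
    """Bulk concentration Cb(z) = Ct + (Co - Ct) exp(-2Kz/(Rv U))."""
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(z_arr < 0) or np.any(z_arr > vessel.length):
        raise DomainError(f"z must lie in [0, L={vessel.length:g}]")
    cb = coeffs.ct + (c0 - coeffs.ct) * np.exp(-_decay_rate(vessel, coeffs) * z_arr)
    return float(cb[0]) if np.isscalar(z) else cb


def wall_flux(coeffs: TransportCoefficients, cb) -> np.ndarray | float:
    """Liposome flux through the wall, Nr = K (Cb - Ct)."""
    cb_arr = np.atleast_1d(np.asarray(cb, dtype=float))
    nr = overall_coefficient(coeffs) * (cb_arr - coeffs.ct)
    return float(nr[0]) if np.isscalar(cb) else nr


def delivered_fraction(
    vessel: VesselSpec, coeffs: TransportCoefficients, c0: float
) -> float:
    """Fraction of inlet liposomes delivered over the vessel length.

    Defined as 1 - Cb(L)/Co with a perfect tissue sink; a finite tissue
    concentration would make the metric ambiguous and is rejected.
    """
    if coeffs.ct != 0:
        raise ValidationError(
            "delivered_fraction is defined only for ct = 0 (perfect sink)"
        )
    if not c0 > 0:
        raise ValidationError(f"c0 must be positive, got {c0!r}")
    return 1.0 - math.exp(-_decay_rate(vessel, coeffs) * vessel.length)


def axial_profile(
    vessel: VesselSpec,
    coeffs: TransportCoefficients,
    c0: float,
    n_points: int = 200,
) -> "Profile":
    """Cb(z) and wall flux Nr(z) on a uniform axial grid as a Profile."""
    from .profiles import Profile

    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    z = np.linspace(0.0, vessel.length, n_points)
    cb = bulk_concentration(vessel, coeffs, c0, z)
    nr = wall_flux(coeffs, cb)
    return Profile(
        coord_name="z_m",
        coords=z,
        series={"cb": cb, "nr": nr},
        metadata={
            "model": "vascular_transport",
            "radius_m": vessel.radius,
            "viscosity_pas": vessel.viscosity,
            "length_m": vessel.length,
            "mean_velocity_ms": vessel.U,
            "kc_ms": coeffs.kc,
            "km_ms": coeffs.km,
            "kt_ms": coeffs.kt,
            "ct": coeffs.ct,
            "c0": c0,
            "overall_K_ms": overall_coefficient(coeffs),
        },
    )
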