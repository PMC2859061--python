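"""Seeded random parameter sets within documented plausible ranges.

Used by the property-test suites and the screening examples.  Ranges are
deliberately broad but physical: vesicle radii span small unilamellar to
giant multilamellar vesicles, diffusivities span small molecules in
water down to hindered macromolecular diffusion in lipid stacks, and the
Biot number is sampled log-uniformly over [1e-3, 1e3] so both the
lumped-capacity and absorbing-surface regimes are exercised.  Vessel
radii span capillaries to small arteries at physiological blood
viscosity; reactor scales are lab-bench microreactor values.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .leakage import MLVSpec
from .reactor import FeedState, ReactorSpec
from .vascular import TransportCoefficients, VesselSpec

__all__ = [
    "random_mlv_specs",
    "random_vascular_scenarios",
    "random_reactor_scenarios",
    "generate_fixtures",
    "BIOT_RANGE",
]

BIOT_RANGE = (1e-3, 1e3)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_mlv_specs(seed, n: int) -> list[MLVSpec]:
    """MLV parameter sets with Biot numbers log-uniform in BIOT_RANGE."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    specs = []
    for _ in range(n):
        radius = 10 ** rng.uniform(-7.3, -5.0)          # 50 nm .. 10 um
        diffusivity = 10 ** rng.uniform(-14.0, -10.0)   # m^2/s
        bi = 10 ** rng.uniform(np.log10(BIOT_RANGE[0]), np.log10(BIOT_RANGE[1]))
        kc = bi * diffusivity / radius
        c0 = rng.uniform(0.1, 10.0)
        specs.append(MLVSpec(radius, diffusivity, kc, c0))
    return specs


def random_vascular_scenarios(
    seed, n: int
) -> list[tuple[VesselSpec, TransportCoefficients, float]]:
    """(vessel, coefficients, inlet concentration) triples, tissue sink.

    The dimensionless axial decay extent 2*K*L/(Rv*U) is sampled
    log-uniformly over [1e-2, 10] (delivered fractions ~1% to ~99.995%)
    and the vessel length derived from it: outside that window the
    outcome is numerically indistinguishable from "nothing delivered" or
    "everything delivered" and carries no information.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    out = []
    for _ in range(n):
        radius = 10 ** rng.uniform(np.log10(5e-6), np.log10(5e-3))
        viscosity = rng.uniform(2e-3, 5e-3)             # blood, Pa s
        u = 10 ** rng.uniform(-4.0, -1.0)               # capillary..artery, m/s
        ks = 10 ** rng.uniform(-8.0, -4.0, size=3)
        coeffs = TransportCoefficients(kc=ks[0], km=ks[1], kt=ks[2], ct=0.0)
        K = 1.0 / np.sum(1.0 / ks)
        extent = 10 ** rng.uniform(-2.0, 1.0)
        length = extent * radius * u / (2.0 * K)
        vessel = VesselSpec(
            radius=radius, viscosity=viscosity, length=length, mean_velocity=u
        )
        c0 = rng.uniform(0.1, 10.0)
        out.append((vessel, coeffs, c0))
    return out


def random_reactor_scenarios(
    seed, n: int
) -> list[tuple[ReactorSpec, FeedState]]:
    """(reactor, feed) pairs with non-negative feeds."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    out = []
    for _ in range(n):
        diameter = 10 ** rng.uniform(-3.0, -2.0)        # 1 mm .. 1 cm tube
        flow = 10 ** rng.uniform(-9.0, -6.0)            # uL/s .. mL/s
        c = (np.pi * diameter**2 / 4.0) / flow
        # Choose k so the dimensionless extent nu_drg*c*k*TR0*L is O(1-100).
        length = rng.uniform(0.05, 2.0)
        tr0 = rng.uniform(10.0, 1000.0)
        k = 10 ** rng.uniform(0.0, 2.0) / (1e4 * c * tr0 * length)
        drg0 = rng.uniform(0.0, 1e5)
        del0 = rng.uniform(0.0, 5.0)
        out.append(
            (
                ReactorSpec(diameter=diameter, feed_flow=flow, rate_coeff=k, length=length),
                FeedState(tr=tr0, drg=drg0, del_=del0),
            )
        )
    return out


def generate_fixtures(seed, n: int, scenario: str = "all") -> dict[str, list]:
    """Reproducible random parameter sets per scenario.

    Sub-seeds are derived from ``seed`` with a SeedSequence spawn so the
    three scenario batteries are independent but jointly reproducible.
    """
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(3)
    batteries = {
        "leakage": lambda: random_mlv_specs(sub[0], n),
        "vascular": lambda: random_vascular_scenarios(sub[1], n),
        "reactor": lambda: random_reactor_scenarios(sub[2], n),
    }
    if scenario != "all":
        if scenario not in batteries:
            raise ValidationError(
                f"unknown scenario {scenario!r}; expected one of "
                f"{sorted(batteries)} or 'all'"
            )
        return {scenario: batteries[scenario]()}
    return {name: make() for name, make in batteries.items()}
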