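"""Parameter-sweep screening over the three models.

The models are cheap enough to evaluate that a Cartesian grid over a few
formulation parameters acts as a rapid first-pass filter: rank candidate
compositions by leakage half-time, delivered fraction, or reactor output
before committing any to experiment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .leakage import MLVSpec, time_to_fraction
from .reactor import FeedState, ReactorSpec, simulate
from .vascular import TransportCoefficients, VesselSpec, delivered_fraction

__all__ = ["SweepSpec", "run_sweep", "METRICS"]


def _metric_leakage_half_time(params: dict) -> float:
    spec = MLVSpec(
        radius=params["mlv.radius_m"],
        diffusivity=params["mlv.diffusivity_m2s"],
        surface_coeff=params["mlv.kc_ms"],
        initial_conc=params.get("mlv.c0", 1.0),
    )
    return time_to_fraction(spec, 0.5)


def _metric_delivered_fraction(params: dict) -> float:
    vessel = VesselSpec(
        radius=params["vessel.radius_m"],
        viscosity=params["vessel.viscosity_pas"],
        length=params["vessel.length_m"],
        pressure_gradient=params.get("vessel.dpdz_pam"),
        mean_velocity=params.get("vessel.u_ms"),
    )
    coeffs = TransportCoefficients(
        kc=params["transport.kc_ms"],
        km=params["transport.km_ms"],
        kt=params["transport.kt_ms"],
        ct=0.0,
    )
    return delivered_fraction(vessel, coeffs, params.get("c0", 1.0))


def _metric_del_at_exit(params: dict) -> float:
    reactor = ReactorSpec(
        diameter=params["reactor.diameter_m"],
        feed_flow=params["reactor.flow_m3s"],
        rate_coeff=params["reactor.k"],
        length=params["reactor.length_m"],
    )
    feed = FeedState(
        tr=params.get("feed.tr", 0.0),
        drg=params.get("feed.drg", 0.0),
        del_=params.get("feed.del", 0.0),
    )
    return float(simulate(reactor, feed, n_points=2).del_[-1])


METRICS = {
    "leakage_half_time": _metric_leakage_half_time,
    "delivered_fraction": _metric_delivered_fraction,
    "del_at_exit": _metric_del_at_exit,
}


@dataclass
class SweepSpec:
    """Cartesian-product sweep definition.

    ``grids`` maps a config-style parameter name to the list of values
    to scan; ``fixed`` holds the parameters common to every combination;
    ``metrics`` names entries of :data:`METRICS` (the first one ranks
    the table).
    """

    grids: dict[str, list]
    metrics: list[str]
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        problems = []
        if not self.grids:
            problems.append("at least one swept parameter is required")
        for name, values in self.grids.items():
            if len(values) < 1:
                problems.append(f"grid for {name!r} is empty")
        if not self.metrics:
            problems.append("at least one metric is required")
        for m in self.metrics:
            if m not in METRICS:
                problems.append(
                    f"unknown metric {m!r}; registered: {sorted(METRICS)}"
                )
        if problems:
            raise ValidationError("; ".join(problems))


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate every grid combination and rank by the first metric.

    Returns one row per combination with parameter columns, metric
    columns, and an ``error`` column.  Rows where a metric fails are
    flagged (NaN metric, error message) and the sweep continues.  The
    table is sorted by the first metric, best (largest) first, ties
    broken lexicographically on the parameter values so the ordering is
    deterministic.
    """
    names = list(spec.grids)
    rows = []
    for combo in itertools.product(*(spec.grids[n] for n in names)):
        params = dict(spec.fixed)
        params.update(dict(zip(names, combo)))
        row: dict = dict(zip(names, combo))
        row["error"] = ""
        for metric in spec.metrics:
            try:
                row[metric] = METRICS[metric](params)
            except Exception as exc:  # keep sweeping; flag the row
                row[metric] = float("nan")
                row["error"] = f"{metric}: {exc}"
        rows.append(row)
    frame = pd.DataFrame(rows, columns=[*names, *spec.metrics, "error"])
    frame = frame.sort_values(
        by=[spec.metrics[0], *names],
        ascending=[False] + [True] * len(names),
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    return frame
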