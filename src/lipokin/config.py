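"""Flat key-value run configuration.

One deliberately simple dialect -- ``key = value`` lines, ``#`` comments,
no nesting -- so that a run can be replayed bit-exactly from the config
echoed into its own output.  Unknown, missing and ill-typed keys are all
reported together in a single error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .reactor import REFERENCE_FEED

__all__ = ["RunConfig", "load_config", "parse_flat", "SCENARIO_KEYS"]

_BOOL = {"true": True, "false": False, "yes": True, "no": False, "1": True, "0": False}

# scenario -> {key: (type, required)}
SCENARIO_KEYS: dict[str, dict[str, tuple[type, bool]]] = {
    "leakage": {
        "mlv.radius_m": (float, True),
        "mlv.diffusivity_m2s": (float, True),
        "mlv.kc_ms": (float, True),
        "mlv.c0": (float, False),
        "solver.n_terms": (int, False),
        "solver.tol": (float, False),
    },
    "vascular": {
        "vessel.radius_m": (float, True),
        "vessel.viscosity_pas": (float, True),
        "vessel.dpdz_pam": (float, False),
        "vessel.u_ms": (float, False),
        "vessel.length_m": (float, True),
        "transport.kc_ms": (float, True),
        "transport.km_ms": (float, True),
        "transport.kt_ms": (float, True),
        "transport.ct": (float, False),
    },
    "reactor": {
        "reactor.diameter_m": (float, True),
        "reactor.flow_m3s": (float, True),
        "reactor.k": (float, True),
        "reactor.length_m": (float, True),
        "feed.tr": (float, False),
        "feed.drg": (float, False),
        "feed.del": (float, False),
        "reference_feed": (bool, False),
    },
}

_DEFAULTS: dict[str, dict[str, object]] = {
    "leakage": {"mlv.c0": 1.0, "solver.n_terms": 200, "solver.tol": 1e-12},
    "vascular": {"transport.ct": 0.0},
    "reactor": {"feed.tr": 0.0, "feed.drg": 0.0, "feed.del": 0.0, "reference_feed": False},
}


@dataclass
class RunConfig:
    """Validated parameters for one scenario run."""

    scenario: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    out: str | None = None
    log_level: str = "info"

    def get(self, key: str, default=None):
        return self.params.get(key, default)


def parse_flat(text: str) -> dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment."""
    out: dict[str, str] = {}
    problems = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            problems.append(f"line {lineno}: expected 'key = value', got {raw.strip()!r}")
            continue
        key, value = (part.strip() for part in line.split("=", 1))
        if key in out:
            problems.append(f"line {lineno}: duplicate key {key!r}")
            continue
        out[key] = value
    if problems:
        raise ConfigError("; ".join(problems))
    return out


def _coerce(key: str, raw: str, typ: type):
    try:
        if typ is bool:
            return _BOOL[raw.lower()]
        return typ(raw)
    except (ValueError, KeyError):
        raise ConfigError(
            f"key {key!r}: cannot interpret {raw!r} as {typ.__name__}"
        ) from None


def load_config(path, scenario: str | None = None) -> RunConfig:
    """Load and validate a flat config file for one scenario.

    The scenario may be given by a ``scenario`` key in the file or by
    the ``scenario`` argument (the CLI subcommand); the argument wins if
    both agree is required.  All problems -- unknown keys, missing
    required keys, ill-typed values -- are collected and reported at
    once.
    """
    text = Path(path).read_text()
    raw = parse_flat(text)

    file_scenario = raw.pop("scenario", None)
    scenario = scenario or file_scenario
    if scenario is None:
        raise ConfigError("no scenario given (add a 'scenario' key or pass one)")
    if file_scenario is not None and scenario != file_scenario:
        raise ConfigError(
            f"config declares scenario {file_scenario!r} but {scenario!r} was requested"
        )
    if scenario not in SCENARIO_KEYS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIO_KEYS)}"
        )

    seed = raw.pop("seed", None)
    out = raw.pop("out", None)
    log_level = raw.pop("log_level", "info")

    schema = SCENARIO_KEYS[scenario]
    problems: list[str] = []
    params: dict[str, object] = dict(_DEFAULTS[scenario])

    for key, value in raw.items():
        if key not in schema:
            problems.append(f"unknown key {key!r} for scenario {scenario!r}")
            continue
        typ, _required = schema[key]
        try:
            params[key] = _coerce(key, value, typ)
        except ConfigError as exc:
            problems.append(str(exc))

    for key, (typ, required) in schema.items():
        if required and key not in params:
            problems.append(f"missing required key {key!r}")

    if scenario == "vascular":
        has_dpdz = "vessel.dpdz_pam" in params
        has_u = "vessel.u_ms" in params
        if has_dpdz == has_u:
            problems.append(
                "exactly one of 'vessel.dpdz_pam' or 'vessel.u_ms' must be given"
            )
    if scenario == "reactor" and params.get("reference_feed"):
        params["feed.tr"] = REFERENCE_FEED.tr
        params["feed.drg"] = REFERENCE_FEED.drg
        params["feed.del"] = REFERENCE_FEED.del_

    # Range sanity for keys that must be positive; model constructors
    # re-validate, but naming the config key here is friendlier.
    positive = {
        "mlv.radius_m", "mlv.diffusivity_m2s", "mlv.kc_ms", "mlv.c0",
        "vessel.radius_m", "vessel.viscosity_pas", "vessel.length_m",
        "transport.kc_ms", "transport.km_ms", "transport.kt_ms",
        "reactor.diameter_m", "reactor.flow_m3s", "reactor.k", "reactor.length_m",
    }
    for key in positive & params.keys():
        if not params[key] > 0:  # type: ignore[operator]
            problems.append(f"key {key!r} must be positive, got {params[key]!r}")

    if problems:
        raise ConfigError("; ".join(problems))

    return RunConfig(
        scenario=scenario,
        params=params,
        seed=int(seed) if seed is not None else None,
        out=out,
        log_level=log_level,
    )
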