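"""Generic sampled-curve container and deterministic CSV/JSON writers.

All solver outputs (leakage curves, axial vessel profiles, reactor
profiles) are returned as a :class:`Profile`: one independent coordinate
grid plus one or more named dependent series.  Writers are deterministic:
fixed column order, 12 significant digits, ``.`` decimal separator and
``\\n`` line endings, so two runs from the same configuration produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Profile", "write_profile", "read_profile_csv"]

_FMT = "%.12g"


@dataclass
class Profile:
    """A sampled curve: coordinate grid plus named dependent series.

    Parameters
    ----------
    coord_name : str
        Column name of the independent coordinate (e.g. ``"t_seconds"``).
    coords : ndarray
        Monotone coordinate grid.
    series : dict of str -> ndarray
        Dependent series, each the same length as ``coords``.  Insertion
        order fixes the column order of every writer.
    metadata : dict
        Free-form provenance (config echo, seed, tool version); embedded
        in JSON output.
    """

    coord_name: str
    coords: np.ndarray
    series: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 1:
            raise ValidationError("Profile coords must be one-dimensional")
        clean = {}
        for name, values in self.series.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.coords.shape:
                raise ValidationError(
                    f"series {name!r} has length {arr.size}, "
                    f"expected {self.coords.size}"
                )
            clean[name] = arr
        self.series = clean

    @property
    def columns(self) -> list[str]:
        return [self.coord_name, *self.series]

    def column(self, name: str) -> np.ndarray:
        if name == self.coord_name:
            return self.coords
        return self.series[name]

    def to_csv(self, path, include_metadata: bool = False) -> None:
        lines = []
        if include_metadata:
            # Flat key = value comment block so the artifact embeds the
            # configuration that produced it and can be replayed.
            for key, value in self.metadata.items():
                if isinstance(value, (str, int, float, bool)):
                    rendered = _FMT % value if isinstance(value, float) else value
                    lines.append(f"# {key} = {rendered}")
        lines.append(",".join(self.columns))
        cols = [self.coords, *self.series.values()]
        for row in zip(*cols):
            lines.append(",".join(_FMT % v for v in row))
        with open(path, "w", newline="") as fh:
            fh.write("\n".join(lines) + "\n")

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "columns": self.columns,
            "data": {
                name: [float(_FMT % v) for v in self.column(name)]
                for name in self.columns
            },
        }
        with open(path, "w", newline="") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def write_profile(profile: Profile, path, format: str = "csv") -> None:
    """Write ``profile`` to ``path`` as ``csv`` or ``json``."""
    if format == "csv":
        profile.to_csv(path)
    elif format == "json":
        profile.to_json(path)
    else:
        raise ValidationError(f"unknown output format {format!r}")


def read_profile_csv(path, coord_name: str | None = None) -> Profile:
    """Read a CSV written by :meth:`Profile.to_csv` back into a Profile."""
    with open(path) as fh:
        header = fh.readline().strip()
        while header.startswith("#"):
            header = fh.readline().strip()
        if not header:
            raise ValidationError(f"{path}: empty file, expected a header row")
        names = header.split(",")
        rows = [line.strip().split(",") for line in fh if line.strip()]
    data = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(names)))
    )
    coord = coord_name or names[0]
    idx = names.index(coord)
    series = {
        name: data[:, i] for i, name in enumerate(names) if i != idx
    }
    return Profile(coord_name=coord, coords=data[:, idx], series=series)
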