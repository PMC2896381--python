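"""Named 3D landmark annotations with CSV persistence.

Landmarks are named, colored points in the local calibrated (µm)
coordinates of the content they annotate, displayed as small spheres. A
:class:`LandmarkSet` keeps them ordered and uniquely named; it can be saved
to and reloaded from a plain-text CSV with the header ``name,x,y,z,r,g,b``
(positions in µm, colors in [0, 1]). The display radius is a viewing
property and is not persisted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import LandmarkParseError, NameCollisionError, NotFoundError

__all__ = ["Landmark", "LandmarkSet", "save_landmarks", "load_landmarks"]

_HEADER = ["name", "x", "y", "z", "r", "g", "b"]


@dataclass
class Landmark:
    name: str
    position: np.ndarray
    color: tuple = (1.0, 0.0, 0.0)
    radius: float = 1.0  # display sphere radius, µm

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("landmark position must be a finite 3-vector")
        if self.radius <= 0:
            raise ValueError("landmark radius must be positive")


class LandmarkSet:
    """Ordered, uniquely named landmarks attached to one content."""

    def __init__(self, owner: str = ""):
        self.owner = owner
        self._marks: dict[str, Landmark] = {}

    def add(self, name: str, position, color=(1.0, 0.0, 0.0), radius: float = 1.0) -> Landmark:
        if name in self._marks:
            raise NameCollisionError(f"landmark '{name}' already exists")
        mark = Landmark(name, position, tuple(color), radius)
        self._marks[name] = mark
        return mark

    def get(self, name: str) -> Landmark:
        try:
            return self._marks[name]
        except KeyError:
            raise NotFoundError(f"no landmark named '{name}'") from None

    def remove(self, name: str) -> None:
        if name not in self._marks:
            raise NotFoundError(f"no landmark named '{name}'")
        del self._marks[name]

    def rename(self, old: str, new: str) -> None:
        """Rename in place; position, color and radius are untouched."""
        if old not in self._marks:
            raise NotFoundError(f"no landmark named '{old}'")
        if new != old and new in self._marks:
            raise NameCollisionError(f"landmark '{new}' already exists")
        items = []
        for name, mark in self._marks.items():
            if name == old:
                mark.name = new
                items.append((new, mark))
            else:
                items.append((name, mark))
        self._marks = dict(items)

    def names(self) -> list[str]:
        return list(self._marks)

    def positions(self) -> np.ndarray:
        if not self._marks:
            return np.zeros((0, 3))
        return np.array([m.position for m in self._marks.values()])

    def __iter__(self):
        return iter(self._marks.values())

    def __len__(self):
        return len(self._marks)

    def __contains__(self, name):
        return name in self._marks


def save_landmarks(lset: LandmarkSet, path) -> None:
    """Write landmarks as CSV ``name,x,y,z,r,g,b``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for m in lset:
            writer.writerow(
                [m.name, *(f"{v:.9g}" for v in m.position), *(f"{c:.9g}" for c in m.color)]
            )


def load_landmarks(path, owner: str = "") -> LandmarkSet:
    """Read a landmark CSV written by :func:`save_landmarks`.

    Raises :class:`LandmarkParseError` (with the line number) on malformed
    rows or a wrong column count.
    """
    lset = LandmarkSet(owner=owner)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1:
                if [c.strip().lower() for c in row] != _HEADER:
                    raise LandmarkParseError(
                        f"expected header '{','.join(_HEADER)}', got '{','.join(row)}'",
                        lineno,
                    )
                continue
            if len(row) != 7:
                raise LandmarkParseError(
                    f"expected 7 columns, got {len(row)}", lineno
                )
            name = row[0]
            try:
                x, y, z, r, g, b = (float(v) for v in row[1:])
            except ValueError:
                raise LandmarkParseError(
                    f"non-numeric coordinate or color in row '{','.join(row)}'",
                    lineno,
                ) from None
            try:
                lset.add(name, (x, y, z), color=(r, g, b))
            except NameCollisionError:
                raise LandmarkParseError(f"duplicate landmark name '{name}'", lineno) from None
    return lset
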