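"""Minimal reader for legacy-ASCII VTK polydata centerlines.

Vascular centerline exports are commonly distributed as legacy VTK polydata
files holding one or more polylines (``POINTS`` + ``LINES``), optionally
with a per-point scalar such as a maximal-inscribed-sphere radius.  Only
that subset is parsed here; arc lengths are computed as summed chord
lengths.  The resulting skeleton can override the default trunk length and
tortuosity of the idealized tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class VTKParseError(ValueError):
    """Malformed legacy VTK input; message carries the line number."""


class EmptyGeometryError(ValueError):
    """The polydata holds no polylines."""


@dataclass
class Polyline:
    points: np.ndarray            # (n, 3) [m]
    radii: np.ndarray | None      # (n,) [m] or None

    @property
    def arc_length(self) -> float:
        """Summed chord length along the polyline [m]."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def straight_distance(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tortuosity(self) -> float:
        d = self.straight_distance
        return self.arc_length / d if d > 0 else float("inf")


@dataclass
class CenterlineSkeleton:
    """Polylines read from a centerline file; the longest one is taken as
    the aortic trunk."""

    polylines: list[Polyline]

    @property
    def trunk(self) -> Polyline:
        return max(self.polylines, key=lambda p: p.arc_length)

    @property
    def trunk_arc_length(self) -> float:
        return self.trunk.arc_length


class _Tokens:
    """Whitespace tokens with line tracking for error messages."""

    def __init__(self, text: str):
        self.items: list[tuple[str, int]] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            for tok in line.split():
                self.items.append((tok, lineno))
        self.pos = 0

    def peek(self) -> str | None:
        return self.items[self.pos][0] if self.pos < len(self.items) else None

    def next(self, what: str = "token") -> str:
        if self.pos >= len(self.items):
            raise VTKParseError(f"unexpected end of file while reading {what}")
        tok, _ = self.items[self.pos]
        self.pos += 1
        return tok

    def next_number(self, what: str) -> float:
        tok = self.next(what)
        try:
            return float(tok)
        except ValueError:
            _, lineno = self.items[self.pos - 1]
            raise VTKParseError(
                f"expected a number for {what}, got {tok!r} at line {lineno}") from None

    def next_int(self, what: str) -> int:
        return int(self.next_number(what))


def read_centerline_vtk(path: str | Path) -> CenterlineSkeleton:
    """Parse a legacy-ASCII VTK polydata file of centerline polylines."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].lstrip().startswith("# vtk DataFile"):
        raise VTKParseError("missing '# vtk DataFile' header at line 1")
    if len(lines) < 3 or lines[2].strip().upper() != "ASCII":
        raise VTKParseError("only ASCII legacy VTK is supported (line 3)")

    body = "\n".join(lines[3:])
    toks = _Tokens(body)
    if toks.next("DATASET keyword").upper() != "DATASET" or \
            toks.next("dataset type").upper() != "POLYDATA":
        raise VTKParseError("expected 'DATASET POLYDATA' at line 4")

    points: np.ndarray | None = None
    conn: list[np.ndarray] = []
    scalars: np.ndarray | None = None

    while toks.peek() is not None:
        key = toks.next().upper()
        if key == "POINTS":
            n = toks.next_int("point count")
            toks.next("points dtype")
            data = np.array([toks.next_number("point coordinate")
                             for _ in range(3 * n)])
            points = data.reshape(n, 3)
        elif key == "LINES":
            n_cells = toks.next_int("line cell count")
            toks.next_int("lines size")
            for _ in range(n_cells):
                k = toks.next_int("polyline point count")
                conn.append(np.array([toks.next_int("point index")
                                      for _ in range(k)]))
        elif key == "POINT_DATA":
            toks.next_int("point-data count")
        elif key == "SCALARS":
            toks.next("scalar name")
            toks.next("scalar dtype")
            if toks.peek() and toks.peek().upper() == "LOOKUP_TABLE":
                toks.next()
                toks.next("lookup table name")
            if points is None:
                raise VTKParseError("SCALARS before POINTS")
            scalars = np.array([toks.next_number("scalar value")
                                for _ in range(len(points))])
        else:
            # skip unrecognized sections token-by-token until a known keyword
            continue

    if points is None:
        raise VTKParseError("no POINTS section found")
    if not conn:
        raise EmptyGeometryError("polydata holds no polylines (LINES section)")

    polylines = []
    for idx in conn:
        if idx.max() >= len(points) or idx.min() < 0:
            raise VTKParseError("polyline references a point index out of range")
        polylines.append(Polyline(
            points=points[idx],
            radii=scalars[idx] if scalars is not None else None))
    return CenterlineSkeleton(polylines=polylines)
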