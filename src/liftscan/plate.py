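"""Six-well plate geometry, synthetic cell positions, and cell XML I/O.

The shared coordinate convention across the package: origin at the corner
of the usable scan area nearest well A1, x along the long (120 mm) axis,
y along the short (80 mm) axis, all lengths in mm.

The synthetic generator distributes cells uniformly within the wells of a
standard-footprint six-well plate (well chosen uniformly, position uniform
over the well disk) and serializes them as a small XML file — the same
harness used to benchmark the continuous scan against stop-and-go.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Well",
    "PlateLayout",
    "CellTarget",
    "CellXMLError",
    "standard_six_well",
    "sample_cells",
    "write_cells_xml",
    "read_cells_xml",
]

# SLAS/ANSI standard plate footprint and common commercial six-well geometry
STANDARD_PLATE_WIDTH_MM = 127.76
STANDARD_PLATE_HEIGHT_MM = 85.48
USABLE_SIZE_MM = (120.0, 80.0)
SIX_WELL_DIAMETER_MM = 34.8
SIX_WELL_PITCH_MM = 39.12


@dataclass(frozen=True)
class Well:
    """One circular well: center (mm) and radius (mm)."""

    cx: float
    cy: float
    radius: float


@dataclass(frozen=True)
class PlateLayout:
    """Plate footprint, usable scan area, and well positions (all mm)."""

    plate_width: float
    plate_height: float
    usable_origin: tuple[float, float]
    usable_size: tuple[float, float]
    wells: tuple[Well, ...]

    def __post_init__(self) -> None:
        if len(self.wells) < 1:
            raise ValueError("a plate layout needs at least one well")
        x0, y0 = self.usable_origin
        lx, ly = self.usable_size
        for i, w in enumerate(self.wells):
            if w.radius <= 0:
                raise ValueError(f"well {i}: radius must be positive")
            inside = (
                w.cx - w.radius >= x0 - 1e-9
                and w.cx + w.radius <= x0 + lx + 1e-9
                and w.cy - w.radius >= y0 - 1e-9
                and w.cy + w.radius <= y0 + ly + 1e-9
            )
            if not inside:
                raise ValueError(f"well {i} extends outside the usable area")


@dataclass(frozen=True)
class CellTarget:
    """A single transfer target: id, stage position (mm), owning well."""

    id: int
    x: float
    y: float
    well_index: int


class CellXMLError(ValueError):
    """Raised when a cell-position XML file is malformed."""


def standard_six_well() -> PlateLayout:
    """Standard six-well plate: 2 x 3 wells, 34.8 mm diameter, 39.12 mm pitch.

    The well grid is centered in the 120 x 80 mm usable area of a
    127.76 x 85.48 mm footprint plate.  Wells are indexed row-major,
    starting at the row nearer the usable-area origin.
    """
    lx, ly = USABLE_SIZE_MM
    r = SIX_WELL_DIAMETER_MM / 2.0
    p = SIX_WELL_PITCH_MM
    cx0, cy0 = lx / 2.0, ly / 2.0
    xs = [cx0 - p, cx0, cx0 + p]
    ys = [cy0 - p / 2.0, cy0 + p / 2.0]
    wells = tuple(Well(x, y, r) for y in ys for x in xs)
    return PlateLayout(
        plate_width=STANDARD_PLATE_WIDTH_MM,
        plate_height=STANDARD_PLATE_HEIGHT_MM,
        usable_origin=(0.0, 0.0),
        usable_size=USABLE_SIZE_MM,
        wells=wells,
    )


def sample_cells(n: int, layout: PlateLayout, seed: int) -> list[CellTarget]:
    """Draw ``n`` cell positions uniformly over the plate's wells.

    Each cell picks a well uniformly at random, then a position uniform
    over that well's disk (sqrt-radius transform).  Deterministic given
    ``seed``: identical inputs reproduce identical coordinates bit for
    bit.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    nw = len(layout.wells)
    wi = rng.integers(0, nw, size=n)
    u = rng.random(n)
    theta = rng.random(n) * (2.0 * np.pi)
    cx = np.array([w.cx for w in layout.wells])
    cy = np.array([w.cy for w in layout.wells])
    rad = np.array([w.radius for w in layout.wells])
    r = rad[wi] * np.sqrt(u)
    x = cx[wi] + r * np.cos(theta)
    y = cy[wi] + r * np.sin(theta)
    return [
        CellTarget(id=i, x=float(x[i]), y=float(y[i]), well_index=int(wi[i]))
        for i in range(n)
    ]


def write_cells_xml(targets: Sequence[CellTarget], path) -> None:
    """Serialize targets as ``<cells><cell id x y well/>...</cells>``.

    Coordinates are written in mm with shortest round-trip formatting, so
    ``read_cells_xml`` recovers them exactly.
    """
    root = ET.Element("cells")
    for t in targets:
        ET.SubElement(
            root,
            "cell",
            id=str(int(t.id)),
            x=repr(float(t.x)),
            y=repr(float(t.y)),
            well=str(int(t.well_index)),
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode" if hasattr(path, "write") else "utf-8",
               xml_declaration=True)


def read_cells_xml(path) -> list[CellTarget]:
    """Parse a cell-position XML file back into :class:`CellTarget` objects.

    Raises
    ------
    CellXMLError
        On malformed XML, a wrong root element, or a ``<cell>`` element
        missing one of the required attributes (named in the message).
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise CellXMLError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "cells":
        raise CellXMLError(f"expected <cells> root element, found <{root.tag}>")
    out: list[CellTarget] = []
    for i, el in enumerate(root.findall("cell")):
        for attr in ("id", "x", "y", "well"):
            if attr not in el.attrib:
                raise CellXMLError(
                    f"<cell> element #{i}: missing required attribute '{attr}'"
                )
        try:
            out.append(
                CellTarget(
                    id=int(el.attrib["id"]),
                    x=float(el.attrib["x"]),
                    y=float(el.attrib["y"]),
                    well_index=int(el.attrib["well"]),
                )
            )
        except ValueError as exc:
            raise CellXMLError(f"<cell> element #{i}: {exc}") from exc
    ids = [t.id for t in out]
    if len(set(ids)) != len(ids):
        raise CellXMLError("duplicate cell ids in file")
    return out
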