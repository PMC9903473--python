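"""Colony morphometry from segmentation masks and stage-coordinate targeting.

A multi-class label image (background, colony, single cell, detached,
differentiated, dead) — the output of an upstream semantic-segmentation
network — is reduced to per-colony records: centroid, area, outer-contour
length, circularity, enclosed inclusions, and the colony's share of its
footprint.  Records serialize to a small XML property list, a rule-based
filter selects transfer candidates, and pixel coordinates convert to
absolute stage coordinates through the image frame (crop offset within
the stitched well image, pixel pitch at the sample, and the stitched
image's stage origin).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.measure import perimeter_crofton as _sk_perimeter

from .plate import CellTarget

__all__ = [
    "DEFAULT_CLASS_MAP",
    "LabelImage",
    "ColonyRecord",
    "ImageFrame",
    "SelectionRules",
    "ColonyXMLError",
    "LabelingError",
    "extract_colonies",
    "pixel_to_stage",
    "stage_to_pixel",
    "check_stitch_tolerance",
    "select_targets",
    "write_colony_xml",
    "read_colony_xml",
    "synth_label_image",
]

# Class values follow the segmentation palette: colonies, single cells,
# detached, differentiated and dead cells over background.
DEFAULT_CLASS_MAP: dict[str, int] = {
    "background": 0,
    "colony": 1,
    "single_cell": 2,
    "detached": 3,
    "differentiated": 4,
    "dead": 5,
}

_STRUCT8 = np.ones((3, 3), dtype=int)  # 8-connectivity for components

COLONY_XML_FIELDS = (
    "id",
    "centerX",
    "centerY",
    "size",
    "length",
    "roundness",
    "childrenSize",
    "colonyPercent",
)


class LabelingError(ValueError):
    """Raised for label images containing undeclared class values."""


class ColonyXMLError(ValueError):
    """Raised when a colony XML property list is malformed."""


@dataclass
class LabelImage:
    """A 2-D integer class raster with its class map (name -> value)."""

    data: np.ndarray
    class_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise LabelingError("label image must be a non-empty 2-D raster")
        declared = set(self.class_map.values())
        present = set(np.unique(arr).tolist())
        unknown = present - declared
        if unknown:
            raise LabelingError(f"undeclared class values in label image: {sorted(unknown)}")
        self.data = arr


@dataclass(frozen=True)
class ColonyRecord:
    """Per-colony morphometry.

    centerX/centerY: centroid in px (0-based, x = column, y = row, pixel
    centers); size: area in px^2; length: outer-contour circumference in
    px; roundness: 4*pi*size/length^2 (1 for a circle); childrenSize:
    total area of enclosed inclusions of other non-background classes;
    colonyPercent: 100 * size / (size + childrenSize).
    """

    id: int
    centerX: float
    centerY: float
    size: int
    length: float
    roundness: float
    childrenSize: int
    colonyPercent: float


@dataclass(frozen=True)
class ImageFrame:
    """Geometry linking a cropped image section to stage coordinates.

    section_offset: pixel offset (x, y) of the crop within the stitched
    well image; pixel_pitch: um per pixel at the sample; well_origin:
    stage coordinates (mm) of the stitched image's pixel (0, 0).
    """

    section_offset: tuple[float, float] = (0.0, 0.0)
    pixel_pitch: float = 1.3
    well_origin: tuple[float, float] = (0.0, 0.0)
    well_index: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass(frozen=True)
class SelectionRules:
    """Optional min/max bounds applied to colony records."""

    min_size: float | None = None
    max_size: float | None = None
    min_roundness: float | None = None
    max_roundness: float | None = None
    min_colony_percent: float | None = None
    max_colony_percent: float | None = None

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_size, self.max_size, "size"),
            (self.min_roundness, self.max_roundness, "roundness"),
            (self.min_colony_percent, self.max_colony_percent, "colony_percent"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"contradictory {name} bounds: min {lo} > max {hi}")

    def accepts(self, rec: ColonyRecord) -> bool:
        checks = (
            (self.min_size, self.max_size, rec.size),
            (self.min_roundness, self.max_roundness, rec.roundness),
            (self.min_colony_percent, self.max_colony_percent, rec.colonyPercent),
        )
        for lo, hi, val in checks:
            if lo is not None and val < lo:
                return False
            if hi is not None and val > hi:
                return False
        return True


def extract_colonies(
    labels: LabelImage,
    class_name: str = "colony",
    roundness_formula: str = "squared",
) -> list[ColonyRecord]:
    """Measure every connected component of the colony class.

    Components are 8-connected and numbered 1.. in raster-scan order of
    their first pixel.  ``length`` is the circumference of the
    hole-filled component estimated with the Crofton perimeter
    (converges to the geometric circumference of the underlying shape,
    so a disk scores roundness ~ 1 and a thin line ~ 0); inner hole
    boundaries are excluded — holes contribute to ``childrenSize``
    instead, counting only pixels of non-background classes other than
    the colony class ("inclusions of a different class").

    ``roundness_formula='literal'`` switches to 4*pi*size/length (the
    non-dimensionless form some reports print) for reproduction purposes.
    """
    if roundness_formula not in ("squared", "literal"):
        raise ValueError("roundness_formula must be 'squared' or 'literal'")
    arr = labels.data
    try:
        colony_val = labels.class_map[class_name]
        bg_val = labels.class_map["background"]
    except KeyError as exc:
        raise LabelingError(f"class map lacks entry {exc}") from exc
    mask = arr == colony_val
    lab, ncomp = ndi.label(mask, structure=_STRUCT8)
    records: list[ColonyRecord] = []
    slices = ndi.find_objects(lab)
    for comp_id in range(1, ncomp + 1):
        sl = slices[comp_id - 1]
        comp = lab[sl] == comp_id
        size = int(comp.sum())
        cy, cx = ndi.center_of_mass(comp)
        cy += sl[0].start
        cx += sl[1].start
        # pad so border-touching components still get a closed contour
        filled = ndi.binary_fill_holes(np.pad(comp, 1))[1:-1, 1:-1]
        length = float(_sk_perimeter(filled, directions=4))
        holes = filled & ~comp
        sub = arr[sl]
        children = int(np.sum(holes & (sub != bg_val) & (sub != colony_val)))
        if roundness_formula == "squared":
            roundness = 4.0 * np.pi * size / length**2 if length > 0 else 0.0
        else:
            roundness = 4.0 * np.pi * size / length if length > 0 else 0.0
        records.append(
            ColonyRecord(
                id=comp_id,
                centerX=float(cx),
                centerY=float(cy),
                size=size,
                length=length,
                roundness=float(roundness),
                childrenSize=children,
                colonyPercent=100.0 * size / (size + children),
            )
        )
    return records


def pixel_to_stage(px_point, frame: ImageFrame) -> tuple[float, float]:
    """Absolute stage position (mm) of a pixel in a cropped section.

    stage = well_origin + (section_offset + pixel) * pitch, with the
    um -> mm conversion applied.
    """
    px, py = px_point
    ox, oy = frame.section_offset
    x0, y0 = frame.well_origin
    f = frame.pixel_pitch * 1e-3  # um/px -> mm/px
    return (x0 + (ox + px) * f, y0 + (oy + py) * f)


def stage_to_pixel(stage_point, frame: ImageFrame) -> tuple[float, float]:
    """Exact inverse of :func:`pixel_to_stage` (continuous pixel coords)."""
    sx, sy = stage_point
    ox, oy = frame.section_offset
    x0, y0 = frame.well_origin
    f = frame.pixel_pitch * 1e-3
    return ((sx - x0) / f - ox, (sy - y0) / f - oy)


def check_stitch_tolerance(shift_um: float, lift_tolerance_um: float = 50.0) -> bool:
    """Whether a stitching shift stays within the LIFT transfer tolerance.

    Stitched frames can be offset by up to ~10 um against each other,
    comfortably inside the 50 um transfer tolerance; returns True iff
    ``shift <= lift_tolerance`` (boundary passes).
    """
    if shift_um < 0:
        raise ValueError("shift must be non-negative")
    return shift_um <= lift_tolerance_um


def select_targets(
    records: Sequence[ColonyRecord],
    rules: SelectionRules | None,
    frame: ImageFrame,
) -> list[CellTarget]:
    """Rule-filter colony records and convert centroids to stage targets.

    Records passing all configured bounds become :class:`CellTarget`
    objects at their centroid's stage position, keeping the record ids.
    An empty/None rule set selects everything.
    """
    rules = rules or SelectionRules()
    out: list[CellTarget] = []
    for rec in records:
        if rules.accepts(rec):
            x, y = pixel_to_stage((rec.centerX, rec.centerY), frame)
            out.append(CellTarget(id=rec.id, x=x, y=y, well_index=frame.well_index))
    return out


def write_colony_xml(records: Sequence[ColonyRecord], path) -> None:
    """Serialize colony records as an XML property list.

    One ``<colony>`` element per record with the canonical attribute
    names (centerX, centerY, size, length, roundness, childrenSize,
    colonyPercent).
    """
    root = ET.Element("colonies")
    for r in records:
        ET.SubElement(
            root,
            "colony",
            id=str(int(r.id)),
            centerX=repr(float(r.centerX)),
            centerY=repr(float(r.centerY)),
            size=str(int(r.size)),
            length=repr(float(r.length)),
            roundness=repr(float(r.roundness)),
            childrenSize=str(int(r.childrenSize)),
            colonyPercent=repr(float(r.colonyPercent)),
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode" if hasattr(path, "write") else "utf-8",
               xml_declaration=True)


def read_colony_xml(path) -> list[ColonyRecord]:
    """Parse a colony XML property list; missing fields name themselves."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ColonyXMLError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "colonies":
        raise ColonyXMLError(f"expected <colonies> root element, found <{root.tag}>")
    out: list[ColonyRecord] = []
    for i, el in enumerate(root.findall("colony")):
        for f in COLONY_XML_FIELDS:
            if f not in el.attrib:
                raise ColonyXMLError(f"<colony> element #{i}: missing field '{f}'")
        out.append(
            ColonyRecord(
                id=int(el.attrib["id"]),
                centerX=float(el.attrib["centerX"]),
                centerY=float(el.attrib["centerY"]),
                size=int(el.attrib["size"]),
                length=float(el.attrib["length"]),
                roundness=float(el.attrib["roundness"]),
                childrenSize=int(el.attrib["childrenSize"]),
                colonyPercent=float(el.attrib["colonyPercent"]),
            )
        )
    return out


@dataclass(frozen=True)
class ShapeTruth:
    """Ground truth returned by :func:`synth_label_image` for one shape."""

    class_name: str
    centroid: tuple[float, float]  # (x, y) px
    area: int


def synth_label_image(
    shapes: Sequence[dict],
    image_shape: tuple[int, int] = (512, 512),
    class_map: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[LabelImage, list[ShapeTruth]]:
    """Rasterize a list of geometric shapes into a synthetic label mask.

    Each shape dict needs ``kind`` ("disk", "ellipse" or "line"),
    ``class`` (a class-map name) and geometry: disks take ``center``
    (row, col) and ``radius``; ellipses ``center``, ``r_radius``,
    ``c_radius`` and optional ``rotation`` (radians); lines ``start`` and
    ``end`` (row, col).  Rasterization is deterministic; ``seed`` is kept
    for interface symmetry with the other generators.  Ground-truth
    centroids ((x, y) px) and pixel areas are returned alongside for
    recovery tests.

    Raises
    ------
    LabelingError
        If shapes of *different* classes overlap (same-class overlaps
        merge silently).
    """
    del seed  # deterministic: no randomized attributes
    cmap = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    bg = cmap["background"]
    arr = np.full(image_shape, bg, dtype=np.uint8)
    truths: list[ShapeTruth] = []
    for i, spec in enumerate(shapes):
        kind = spec["kind"]
        cname = spec["class"]
        val = cmap[cname]
        if kind == "disk":
            rr, cc = skdraw.disk(spec["center"], spec["radius"], shape=image_shape)
        elif kind == "ellipse":
            rr, cc = skdraw.ellipse(
                *spec["center"],
                spec["r_radius"],
                spec["c_radius"],
                rotation=spec.get("rotation", 0.0),
                shape=image_shape,
            )
        elif kind == "line":
            rr, cc = skdraw.line(*spec["start"], *spec["end"])
            keep = (rr >= 0) & (rr < image_shape[0]) & (cc >= 0) & (cc < image_shape[1])
            rr, cc = rr[keep], cc[keep]
        else:
            raise ValueError(f"shape #{i}: unknown kind {kind!r}")
        existing = arr[rr, cc]
        if np.any((existing != bg) & (existing != val)):
            raise LabelingError(f"shape #{i} ({cname}) overlaps a different class")
        arr[rr, cc] = val
        truths.append(
            ShapeTruth(
                class_name=cname,
                centroid=(float(cc.mean()), float(rr.mean())),
                area=int(len(rr)),
            )
        )
    return LabelImage(arr, cmap), truths
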