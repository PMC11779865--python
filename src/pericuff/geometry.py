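"""Membrane-hull handling, perivascular cuff detection and outline registration.

A T-cell cuff is a membrane hull (LAMA2-delimited perivascular region)
whose contained T-cell count is at least 3.  Containment is even-odd
point-in-polygon of the cell centroid with inclusive boundaries; when hulls
are nested the smallest-area containing hull wins, so a cell inside an
annulus hole belongs to the inner structure, not the annulus.

Consecutive-slide tissue outlines are registered rigidly by brute-force
grid search over rotations and translations maximizing the
intersection-over-union, and the consensus outline is the geometric
intersection of the aligned outlines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely import affinity
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .core import CellMap, MembraneHull, equivalent_radius

log = logging.getLogger("pericuff")

__all__ = [
    "Cuff",
    "RegistrationResult",
    "build_hulls",
    "assign_cells_to_hulls",
    "detect_cuffs",
    "area_adjusted_count",
    "classify_roi_phenotype",
    "register_outlines",
]

#: Cuff-size classes by equivalent radius (µm); upper edges of small/medium.
DEFAULT_SIZE_CUTOFFS = (50.0, 100.0)

#: Minimum number of contained T cells for a hull to qualify as a cuff
#: ("more than 2").
MIN_CUFF_T_CELLS = 3


@dataclass
class Cuff:
    """A perivascular T-cell cuff: membrane hull plus its T-cell members."""

    hull: MembraneHull
    member_cell_ids: list[str]
    t_cell_count: int
    area: float
    equivalent_radius: float
    size_class: str

    def __post_init__(self):
        assert self.t_cell_count >= MIN_CUFF_T_CELLS


@dataclass
class RegistrationResult:
    rotation: float  # degrees, applied to the moving outline about its centroid
    dx: float
    dy: float
    iou_before: float
    iou_after: float
    consensus: Polygon  # possibly empty


def _size_class(radius: float, cutoffs=DEFAULT_SIZE_CUTOFFS) -> str:
    if radius <= cutoffs[0]:
        return "small"
    if radius <= cutoffs[1]:
        return "medium"
    return "large"


def build_hulls(
    polygons,
    smoothing: float = 10.0,
    simplify_tolerance: float | None = None,
    marker: str = "LAMA2",
) -> list[MembraneHull]:
    """Merge and smooth raw membrane polygons into closed hulls.

    Morphological closing (buffer out by ``smoothing`` µm, then back in)
    bridges gaps smaller than ~2x the smoothing radius and fills narrow
    inlets, then light vertex simplification removes stair-step artifacts.
    Every input polygon is contained in exactly one output hull.  Degenerate
    (zero-area) inputs are skipped with a warning.
    """
    geoms = []
    for p in polygons:
        g = p.polygon if isinstance(p, MembraneHull) else p
        if g.area <= 0:
            log.warning("degenerate zero-area polygon skipped in build_hulls")
            continue
        geoms.append(g)
    if not geoms:
        return []
    closed = unary_union([g.buffer(smoothing) for g in geoms]).buffer(-smoothing)
    parts = list(closed.geoms) if isinstance(closed, MultiPolygon) else [closed]
    tol = smoothing / 20.0 if simplify_tolerance is None else simplify_tolerance
    hulls = []
    for i, part in enumerate(parts):
        # the polygonal arc approximation of buffering can erode corners a
        # hair inside the inputs; union them back so input ⊆ output holds
        inputs = [g for g in geoms if part.intersects(g)]
        part = unary_union([part] + inputs)
        simplified = part.simplify(tol, preserve_topology=True)
        if any(not simplified.covers(g) for g in inputs):
            simplified = part
        hulls.append(MembraneHull(simplified, marker=marker, hull_id=f"hull_{i}"))
    return hulls


def assign_cells_to_hulls(cells: CellMap, hulls) -> np.ndarray:
    """Hull index per cell (-1 if unassigned).

    Containment is even-odd with inclusive boundaries: a centroid inside a
    hole of an annular hull is NOT contained by it.  A centroid inside
    several nested hulls is assigned to the smallest-area one.
    """
    n = len(cells)
    assigned = np.full(n, -1, dtype=int)
    if n == 0 or len(hulls) == 0:
        return assigned
    geoms = [h.polygon for h in hulls]
    areas = np.array([g.area for g in geoms])
    tree = STRtree(geoms)
    points = [Point(x, y) for x, y in cells.xy]
    cand_cell, cand_hull = tree.query(points, predicate="intersects")
    best_area = np.full(n, np.inf)
    for ci, hi in zip(cand_cell, cand_hull):
        # STRtree 'intersects' on a point vs polygon is covers-equivalent
        if areas[hi] < best_area[ci]:
            best_area[ci] = areas[hi]
            assigned[ci] = hi
    return assigned


def detect_cuffs(
    cells: CellMap,
    hulls,
    t_labels=("CD4T", "CD8T"),
    size_cutoffs=DEFAULT_SIZE_CUTOFFS,
) -> list[Cuff]:
    """Find T-cell cuffs: hulls containing at least 3 T cells.

    ``t_labels`` is the union of phenotypes counted as T cells.  Counts use
    the nested-hull assignment of :func:`assign_cells_to_hulls`, so a T cell
    in the lumen hole of an annulus does not count toward the annulus.
    """
    t_labels = set(t_labels)
    if not t_labels:
        raise ValueError("t_labels must be non-empty")
    t_cells = cells.of_type(t_labels)
    assigned = assign_cells_to_hulls(t_cells, hulls)
    ids = t_cells.df["cell_id"].to_numpy()
    cuffs = []
    for hi, hull in enumerate(hulls):
        members = ids[assigned == hi].tolist()
        if len(members) >= MIN_CUFF_T_CELLS:
            area = hull.area
            cuffs.append(
                Cuff(
                    hull=hull,
                    member_cell_ids=members,
                    t_cell_count=len(members),
                    area=area,
                    equivalent_radius=equivalent_radius(area),
                    size_class=_size_class(equivalent_radius(area), size_cutoffs),
                )
            )
    return cuffs


def area_adjusted_count(cells: CellMap, region, label) -> float:
    """Density of label-cells in a region, in cells per mm².

    ``region`` may be a MembraneHull or any shapely geometry with area; the
    count includes cells whose centroid lies in the region (boundary
    inclusive), divided by the region area converted from µm² to mm².
    """
    geom = region.polygon if isinstance(region, MembraneHull) else region
    if geom.area <= 0:
        raise ValueError("region has zero area")
    if isinstance(label, str):
        label = {label}
    sub = cells.of_type(label)
    k = sum(1 for x, y in sub.xy if geom.covers(Point(x, y)))
    return k / (geom.area * 1e-6)


def classify_roi_phenotype(roi_cells: CellMap, cuffs_in_roi, t_labels=("CD4T", "CD8T")) -> str:
    """Tissue-phenotype call for one ROI: cuff / stromal_T / absent.

    ``cuff`` if at least one detected cuff is present, else ``stromal_T``
    if the ROI holds at least one T cell, else ``absent``.
    """
    if len(list(cuffs_in_roi)) > 0:
        return "cuff"
    if len(roi_cells.of_type(set(t_labels))) > 0:
        return "stromal_T"
    return "absent"


def _iou(a, b) -> float:
    inter = a.intersection(b).area
    if inter == 0:
        return 0.0
    return inter / a.union(b).area


def register_outlines(
    outline_a,
    outline_b,
    angle_range: float = 15.0,
    angle_step: float = 0.5,
    translation_range: float = 500.0,
    translation_step: float = 25.0,
) -> RegistrationResult:
    """Rigidly align outline_b onto outline_a by exhaustive grid search.

    The moving outline is rotated about its own centroid and translated; the
    grid always includes the identity transform, so the aligned IoU can
    never fall below the unaligned one.  The consensus outline is the
    intersection of outline_a with the transformed outline_b.
    """
    a = outline_a.polygon if isinstance(outline_a, MembraneHull) else outline_a
    b = outline_b.polygon if isinstance(outline_b, MembraneHull) else outline_b
    if a.area <= 0 or b.area <= 0:
        raise ValueError("both outlines must have positive area")

    def grid(extent, step):
        n = int(math.floor(extent / step + 1e-9))
        return np.concatenate([-step * np.arange(n, 0, -1), [0.0], step * np.arange(1, n + 1)])

    angles = grid(angle_range, angle_step)
    shifts = grid(translation_range, translation_step)
    iou_before = _iou(a, b)
    best = (iou_before, 0.0, 0.0, 0.0)
    centroid = (b.centroid.x, b.centroid.y)
    for ang in angles:
        rb = affinity.rotate(b, ang, origin=centroid) if ang != 0.0 else b
        # prune translations by bounding-box overlap before polygon clipping
        for dx in shifts:
            for dy in shifts:
                tb = affinity.translate(rb, dx, dy) if (dx or dy) else rb
                iou = _iou(a, tb)
                if iou > best[0]:
                    best = (iou, ang, dx, dy)
    iou_after, ang, dx, dy = best
    aligned = affinity.translate(affinity.rotate(b, ang, origin=centroid), dx, dy)
    consensus = a.intersection(aligned)
    if consensus.is_empty or iou_after == 0.0:
        log.warning("outline registration found no overlap; consensus is empty")
        consensus = Polygon()
    elif isinstance(consensus, MultiPolygon):
        consensus = max(consensus.geoms, key=lambda g: g.area)
    elif not isinstance(consensus, Polygon):
        consensus = Polygon()
    return RegistrationResult(
        rotation=float(ang), dx=float(dx), dy=float(dy),
        iou_before=iou_before, iou_after=iou_after, consensus=consensus,
    )
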