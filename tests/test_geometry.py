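"""Hull construction, cuff detection, densities, ROI calls, registration."""

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Point, Polygon, box

from conftest import make_map
from pericuff import (
    MembraneHull,
    area_adjusted_count,
    assign_cells_to_hulls,
    build_hulls,
    classify_roi_phenotype,
    detect_cuffs,
    register_outlines,
)


def annulus(cx=0.0, cy=0.0, r_in=20.0, r_out=60.0) -> MembraneHull:
    outer = Point(cx, cy).buffer(r_out, quad_segs=64)
    inner = Point(cx, cy).buffer(r_in, quad_segs=64)
    return MembraneHull(outer.difference(inner), marker="LAMA2")


# ---------------------------------------------------------------------------
# build_hulls

def test_convex_square_preserved():
    h = build_hulls([box(0, 0, 50, 50)], smoothing=5)
    assert len(h) == 1
    assert 1.0 - 1e-9 <= h[0].area / 2500.0 <= 1.05
    assert h[0].polygon.covers(box(0, 0, 50, 50))


def test_close_polygons_merged_far_polygons_not():
    near = build_hulls([box(0, 0, 10, 10), box(11, 0, 21, 10)], smoothing=5)
    assert len(near) == 1
    far = build_hulls([box(0, 0, 10, 10), box(110, 0, 120, 10)], smoothing=5)
    assert len(far) == 2


def test_merge_agrees_with_raster_closing_oracle():
    """Connectivity after closing matches binary morphological closing."""
    from scipy import ndimage

    polys = [box(10, 10, 30, 30), box(33, 10, 53, 30), box(80, 60, 95, 90)]
    s = 4.0
    hulls = build_hulls(polys, smoothing=s)
    # raster oracle at 0.5 µm
    res = 0.5
    nx = ny = 220
    mask = np.zeros((ny, nx), bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([(xx.ravel() + 0.5) * res, (yy.ravel() + 0.5) * res])
    for p in polys:
        x0, y0, x1, y1 = p.bounds
        mask |= (
            (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        ).reshape(ny, nx)
    r = int(round(s / res))
    yk, xk = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xk**2 + yk**2) <= r**2
    closed = ndimage.binary_erosion(ndimage.binary_dilation(mask, disk), disk)
    _, n_components = ndimage.label(closed)
    assert len(hulls) == n_components == 2


def test_degenerate_polygon_skipped():
    line_like = Polygon([(0, 0), (10, 0), (10, 0), (0, 0)])
    h = build_hulls([line_like, box(0, 0, 5, 5)], smoothing=2)
    assert len(h) == 1


# ---------------------------------------------------------------------------
# containment and cuffs

def test_hole_cell_not_assigned_ring_cell_assigned():
    a = annulus()
    cells = make_map([(0, 0), (40, 0)], ["CD4T", "CD4T"])
    assigned = assign_cells_to_hulls(cells, [a])
    assert assigned[0] == -1  # lumen hole
    assert assigned[1] == 0  # ring region


def test_nested_hulls_resolve_to_smallest():
    big = MembraneHull(box(0, 0, 100, 100))
    small = MembraneHull(box(40, 40, 60, 60))
    cells = make_map([(50, 50), (10, 10)], ["CD4T", "CD4T"])
    assigned = assign_cells_to_hulls(cells, [big, small])
    assert assigned[0] == 1 and assigned[1] == 0


def test_boundary_point_contained():
    h = MembraneHull(box(0, 0, 10, 10))
    assigned = assign_cells_to_hulls(make_map([(0, 5)], ["CD4T"]), [h])
    assert assigned[0] == 0


def raster_masks(hulls, res=0.5, extent=350.0):
    """Pixel-mask oracle: rasterize exterior minus holes with skimage."""
    from skimage.draw import polygon2mask

    n = int(extent / res)
    masks = []
    for h in hulls:
        ext = np.asarray(h.polygon.exterior.coords) / res  # (x, y) -> (col, row)
        m = polygon2mask((n, n), ext[:, ::-1])
        for hole in h.polygon.interiors:
            m &= ~polygon2mask((n, n), (np.asarray(hole.coords) / res)[:, ::-1])
        masks.append(m)
    return masks


def test_assignment_matches_raster_oracle(rng):
    """Random points vs 3 hulls agree with a 0.5 µm pixel-mask oracle."""
    hulls = [annulus(100, 100, 15, 50), MembraneHull(box(200, 50, 300, 150)), MembraneHull(box(240, 90, 260, 110))]
    pts = rng.uniform(0, 349, (1000, 2))
    cells = make_map(pts, ["CD4T"] * 1000)
    assigned = assign_cells_to_hulls(cells, hulls)
    res = 0.5
    masks = raster_masks(hulls, res=res)
    areas = [h.area for h in hulls]
    boundary_dist = [
        min(
            min(h.polygon.exterior.distance(Point(x, y)) for h in hulls),
            min(
                (ring.distance(Point(x, y)) for h in hulls for ring in h.polygon.interiors),
                default=np.inf,
            ),
        )
        for x, y in pts
    ]
    mismatches = 0
    for i, (x, y) in enumerate(pts):
        row, col = int(y / res), int(x / res)
        cand = [j for j in range(3) if masks[j][row, col]]
        expect = min(cand, key=lambda j: areas[j]) if cand else -1
        if assigned[i] != expect and boundary_dist[i] > 2 * res:
            # disagreement allowed only within the oracle's pixel resolution
            mismatches += 1
    assert mismatches == 0


def test_cuff_rule_requires_more_than_two_t_cells():
    a = annulus()
    two = make_map([(40, 0), (0, 40)], ["CD4T", "CD8T"])
    assert detect_cuffs(two, [a]) == []
    three = make_map([(40, 0), (0, 40), (-40, 0)], ["CD4T", "CD8T", "CD4T"])
    cuffs = detect_cuffs(three, [a])
    assert len(cuffs) == 1 and cuffs[0].t_cell_count == 3


def test_constructed_scene_two_cuffs(rng):
    a1, a2 = annulus(0, 0), annulus(500, 0)
    pts, labs = [], []
    for ang in np.linspace(0, 2 * np.pi, 3, endpoint=False):
        pts.append((40 * np.cos(ang), 40 * np.sin(ang)))
        labs.append("CD4T")
    for ang in np.linspace(0, 2 * np.pi, 5, endpoint=False):
        pts.append((500 + 40 * np.cos(ang), 40 * np.sin(ang)))
        labs.append("CD8T")
    stromal = rng.uniform(100, 400, (10, 2)) + [0, 200]
    pts += [tuple(p) for p in stromal]
    labs += ["CD4T"] * 10
    cells = make_map(pts, labs)
    cuffs = detect_cuffs(cells, [a1, a2])
    assert sorted(c.t_cell_count for c in cuffs) == [3, 5]
    assert all(
        c.hull.contains_point(*cells.xy[list(cells.df["cell_id"]).index(m)])
        for c in cuffs
        for m in c.member_cell_ids
    )
    for c in cuffs:
        assert c.equivalent_radius**2 * np.pi == pytest.approx(c.area, rel=1e-6)


def test_adding_t_cell_inside_cuff_is_monotone(rng):
    a = annulus()
    base = make_map([(40, 0), (0, 40), (-40, 0)], ["CD4T"] * 3)
    c0 = detect_cuffs(base, [a])[0]
    import pandas as pd

    df = pd.concat(
        [base.df, pd.DataFrame([{"cell_id": "extra", "x": 0, "y": -40, "phenotype": "CD8T"}])],
        ignore_index=True,
    )
    from pericuff import CellMap

    c1 = detect_cuffs(CellMap(df), [a])[0]
    assert c1.t_cell_count == c0.t_cell_count + 1


# ---------------------------------------------------------------------------
# densities and ROI calls

def test_area_adjusted_count_simple():
    region = MembraneHull(box(0, 0, 2000, 1000))  # 2 mm²
    cells = make_map([(i * 100 + 50, 500) for i in range(10)], ["CD4T"] * 10)
    assert area_adjusted_count(cells, region, "CD4T") == pytest.approx(5.0)
    assert area_adjusted_count(cells, region, "TAM") == 0.0


def test_cuff_and_stroma_counts_partition(rng):
    tissue = box(0, 0, 1000, 1000)
    cuff_hull = annulus(500, 500, 20, 80)
    pts = rng.uniform(0, 1000, (200, 2))
    cells = make_map(pts, ["CD4T"] * 200)
    stroma = tissue.difference(cuff_hull.polygon)
    in_cuff = area_adjusted_count(cells, cuff_hull, "CD4T") * cuff_hull.area * 1e-6
    in_stroma = area_adjusted_count(cells, stroma, "CD4T") * stroma.area * 1e-6
    total = area_adjusted_count(cells, MembraneHull(tissue), "CD4T") * tissue.area * 1e-6
    assert in_cuff + in_stroma == pytest.approx(total, abs=1e-9)


def test_zero_area_region_errors():
    with pytest.raises(ValueError):
        area_adjusted_count(make_map([(0, 0)], ["A"]), Polygon(), "A")


def test_classify_roi_phenotype_taxonomy():
    a = annulus()
    none = make_map(np.empty((0, 2)), [])
    assert classify_roi_phenotype(none, []) == "absent"
    stromal = make_map([(200, 200)], ["CD8T"])
    assert classify_roi_phenotype(stromal, []) == "stromal_T"
    cuffed = make_map([(40, 0), (0, 40), (-40, 0)], ["CD4T"] * 3)
    assert classify_roi_phenotype(cuffed, detect_cuffs(cuffed, [a])) == "cuff"


# ---------------------------------------------------------------------------
# registration

def test_identical_outlines_identity_transform():
    r = box(0, 0, 400, 150)
    res = register_outlines(r, r, angle_range=5, angle_step=1, translation_range=50, translation_step=25)
    assert (res.rotation, res.dx, res.dy) == (0.0, 0.0, 0.0)
    assert res.iou_after == pytest.approx(1.0)
    assert res.consensus.symmetric_difference(r).area == pytest.approx(0.0, abs=1e-6)


def test_rotation_recovered_within_grid_step():
    r = box(0, 0, 400, 150)
    rotated = affinity.rotate(r, 10, origin="centroid")
    res = register_outlines(r, rotated, angle_range=15, angle_step=1, translation_range=25, translation_step=25)
    assert res.rotation == pytest.approx(-10.0, abs=1.0)
    assert res.iou_after > 0.99
    assert res.iou_after >= res.iou_before


def test_disjoint_far_shapes_empty_consensus():
    a, b = box(0, 0, 10, 10), box(10_000, 0, 10_010, 10)
    res = register_outlines(a, b, angle_range=2, angle_step=1, translation_range=50, translation_step=25)
    assert res.iou_after == 0.0 and res.consensus.is_empty


def test_consensus_subset_of_both_aligned_outlines():
    a = box(0, 0, 200, 100)
    b = affinity.translate(box(0, 0, 200, 100), 30, 10)
    res = register_outlines(a, b, angle_range=2, angle_step=1, translation_range=50, translation_step=10)
    aligned_b = affinity.translate(
        affinity.rotate(b, res.rotation, origin=(b.centroid.x, b.centroid.y)), res.dx, res.dy
    )
    assert a.buffer(1e-6).covers(res.consensus)
    assert aligned_b.buffer(1e-6).covers(res.consensus)
    assert res.iou_after >= res.iou_before
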