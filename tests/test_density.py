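"""KDE fields, corrected density ratio, binning, composition tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_map
from pericuff import (
    GridSpec,
    bin_composition,
    corrected_density,
    density_at_cells,
    kde_field,
    per_cell_corrected_density,
    pooled_equal_count_bins,
)


def test_single_point_integral_unity():
    g = GridSpec.for_points(np.array([[0.0, 0.0]]), sigma=10.0)
    f = kde_field(np.array([[0.0, 0.0]]), 10.0, g)
    assert f.integral() == pytest.approx(1.0, rel=0.01)


def test_field_maximum_at_nearest_node():
    pt = np.array([[33.0, 47.0]])
    g = GridSpec.for_points(pt, sigma=20.0)
    f = kde_field(pt, 20.0, g)
    iy, ix = np.unravel_index(np.argmax(f.values), f.values.shape)
    assert abs(g.xs[ix] - 33.0) <= g.spacing / 2 + 1e-9
    assert abs(g.ys[iy] - 47.0) <= g.spacing / 2 + 1e-9


def test_two_point_field_matches_analytic_sum():
    pts = np.array([[0.0, 0.0], [30.0, 10.0]])
    sig = 15.0
    g = GridSpec.for_points(pts, sig)
    f = kde_field(pts, sig, g)
    for ix in (3, 20, 55):
        for iy in (4, 25, 60):
            gx, gy = g.xs[ix], g.ys[iy]
            analytic = sum(
                np.exp(-((gx - px) ** 2 + (gy - py) ** 2) / (2 * sig**2)) for px, py in pts
            ) / (2 * np.pi * sig**2)
            assert f.values[iy, ix] == pytest.approx(analytic, abs=1e-12)


def test_intensity_integrates_to_point_count(rng):
    pts = rng.uniform(0, 200, (37, 2))
    g = GridSpec.for_points(pts, 25.0)
    f = kde_field(pts, 25.0, g)
    assert f.integral() == pytest.approx(37.0, rel=0.01)


def test_ratio_all_positive_is_one_no_positive_is_zero(rng):
    pts = rng.uniform(0, 100, (50, 2))
    g = GridSpec.for_points(pts, 20.0)
    total = kde_field(pts, 20.0, g)
    ratio1 = corrected_density(kde_field(pts, 20.0, g), total, points=pts)
    assert np.allclose(ratio1.values[ratio1.mask], 1.0)
    ratio0 = corrected_density(kde_field(np.empty((0, 2)), 20.0, g), total, points=pts)
    assert np.allclose(ratio0.values[ratio0.mask], 0.0)


def test_ratio_bounded_zero_one(rng):
    pts = rng.uniform(0, 300, (200, 2))
    pos = pts[rng.uniform(size=200) < 0.3]
    g = GridSpec.for_points(pts, 40.0)
    ratio = corrected_density(kde_field(pos, 40.0, g), kde_field(pts, 40.0, g), points=pts)
    vals = ratio.values[ratio.mask]
    assert vals.min() >= 0.0 and vals.max() <= 1.0


def test_grid_mismatch_rejected(rng):
    pts = rng.uniform(0, 100, (10, 2))
    g1 = GridSpec.for_points(pts, 10.0)
    g2 = GridSpec.for_points(pts, 12.0)
    with pytest.raises(ValueError):
        corrected_density(kde_field(pts, 10.0, g1), kde_field(pts, 12.0, g2))


def test_half_plane_ratio_profile(rng):
    """Left-half positives: ratio ≈ 1 deep left, ≈ 0 deep right, ≈ 0.5 at the boundary."""
    xy = rng.uniform(0, 1000, (3000, 2))
    pos = xy[xy[:, 0] < 500]
    g = GridSpec.for_points(xy, 100.0)
    ratio = corrected_density(kde_field(pos, 100.0, g), kde_field(xy, 100.0, g), points=xy)
    probes = np.array([[100.0, 500.0], [900.0, 500.0], [500.0, 500.0]])
    vals, defined = density_at_cells(ratio, probes)
    assert defined.all()
    assert vals[0] == pytest.approx(1.0, abs=0.05)
    assert vals[1] == pytest.approx(0.0, abs=0.05)
    assert vals[2] == pytest.approx(0.5, abs=0.05)


def test_planted_proportion_recovered(rng):
    """Independent positive labeling at probability p gives interior ratio ≈ p."""
    p = 0.35
    errs = []
    for seed in range(10):
        r = np.random.default_rng(seed)
        xy = r.uniform(0, 1500, (500, 2))
        pos = xy[r.uniform(size=500) < p]
        g = GridSpec.for_points(xy, 200.0)
        ratio = corrected_density(kde_field(pos, 200.0, g), kde_field(xy, 200.0, g), points=xy)
        interior = (
            (g.xs[None, :] > 300) & (g.xs[None, :] < 1200) & (g.ys[:, None] > 300) & (g.ys[:, None] < 1200)
        )
        errs.append(ratio.values[interior & ratio.mask].mean() - p)
    assert abs(np.mean(errs)) < 0.05


def test_scale_equivariance(rng):
    """Scaling coordinates and sigma by c leaves the ratio at matched points unchanged."""
    xy = rng.uniform(0, 400, (200, 2))
    pos_mask = rng.uniform(size=200) < 0.4
    c = 3.0
    out = []
    for scale in (1.0, c):
        g = GridSpec.for_points(xy * scale, 50.0 * scale)
        ratio = corrected_density(
            kde_field(xy[pos_mask] * scale, 50.0 * scale, g),
            kde_field(xy * scale, 50.0 * scale, g),
            points=xy * scale,
        )
        vals, defined = density_at_cells(ratio, xy * scale)
        out.append(vals[defined])
    np.testing.assert_allclose(out[0], out[1], atol=1e-9)


def test_cell_on_node_and_midpoint_interpolation():
    g = GridSpec(0.0, 0.0, 10.0, 3, 3)
    values = np.arange(9, dtype=float).reshape(3, 3)
    from pericuff import DensityField

    f = DensityField(g, values, sigma=1.0, kind="intensity")
    v, d = density_at_cells(f, np.array([[10.0, 10.0], [5.0, 5.0], [100.0, 0.0]]))
    assert v[0] == pytest.approx(values[1, 1])
    assert v[1] == pytest.approx((values[0, 0] + values[0, 1] + values[1, 0] + values[1, 1]) / 4)
    assert not d[2] and np.isnan(v[2])  # outside the grid: flagged


def test_per_cell_values_match_gridless_kernel_sum(rng):
    """Interpolated ratio matches direct kernel-sum recomputation within 2%."""
    xy = rng.uniform(0, 500, (300, 2))
    labels = np.where(rng.uniform(size=300) < 0.4, "GTC", "TumorCell")
    cm = make_map(xy, labels)
    sig = 100.0
    vals, defined = per_cell_corrected_density(cm, "GTC", sigma=sig, spacing=sig / 10)
    pos = xy[labels == "GTC"]
    probe = rng.choice(300, 100, replace=False)
    for i in probe:
        num = np.exp(-((pos - xy[i]) ** 2).sum(axis=1) / (2 * sig**2)).sum()
        den = np.exp(-((xy - xy[i]) ** 2).sum(axis=1) / (2 * sig**2)).sum()
        assert defined[i]
        assert vals[i] == pytest.approx(num / den, rel=0.02)


# ---------------------------------------------------------------------------
# binning

def test_equal_count_bins_exact_sizes(rng):
    vals = rng.normal(size=40)
    bins = pooled_equal_count_bins(vals, 20)
    counts = np.bincount(bins)[1:]
    assert (counts == 2).all()


def test_pigeonhole_41_values():
    vals = np.arange(41, dtype=float)
    bins = pooled_equal_count_bins(vals, 20)
    counts = np.bincount(bins)[1:]
    assert sorted(counts) == [2] * 19 + [3]
    assert counts[0] == 3  # the extra cell lands in the lowest bin
    assert bins[0] == 1 and bins[40] == 20  # ordered by value


def test_ties_broken_by_stable_order():
    vals = np.ones(10)
    bins = pooled_equal_count_bins(vals, 5)
    np.testing.assert_array_equal(bins, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])


def test_nan_values_get_bin_zero():
    vals = np.array([1.0, np.nan, 2.0, 3.0, np.nan, 4.0])
    bins = pooled_equal_count_bins(vals, 2)
    assert bins[1] == 0 and bins[4] == 0
    assert sorted(np.bincount(bins)[1:]) == [2, 2]


def test_too_few_values_errors():
    with pytest.raises(ValueError):
        pooled_equal_count_bins(np.array([1.0, 2.0]), 5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 20))
def test_bin_occupancy_never_spreads_beyond_one(seed, n_bins):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_bins, 200))
    vals = rng.normal(size=n)
    bins = pooled_equal_count_bins(vals, n_bins)
    counts = np.bincount(bins, minlength=n_bins + 1)[1:]
    assert counts.sum() == n
    assert counts.max() - counts.min() <= 1
    # ordering by value is exact
    order = np.argsort(vals, kind="stable")
    assert (np.diff(bins[order]) >= 0).all()


# ---------------------------------------------------------------------------
# composition table

def test_single_group_fraction_one(rng):
    cm = make_map(rng.uniform(0, 100, (40, 2)), ["CD4T"] * 20 + ["TAM"] * 20)
    bins = pooled_equal_count_bins(rng.uniform(size=40), 4)
    table = bin_composition(bins, cm, densities=rng.uniform(size=40))
    assert (table["group_fraction"] == 1.0).all()
    assert len(table) == 4


def test_phenotype_fractions_sum_to_one_within_covered_set(rng):
    labels = rng.choice(["CD4T", "CD8T", "TAM"], 60)
    cm = make_map(rng.uniform(0, 100, (60, 2)), labels)
    bins = pooled_equal_count_bins(rng.uniform(size=60), 3)
    table = bin_composition(bins, cm, phenotypes_of_interest=("CD4T", "CD8T", "TAM"))
    sums = table[["frac_CD4T", "frac_CD8T", "frac_TAM"]].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0)


def test_unknown_sample_group_rejected(rng):
    import pandas as pd

    from pericuff import CellMap

    df = pd.DataFrame(
        {"cell_id": ["a", "b"], "x": [0, 1], "y": [0, 1], "phenotype": ["CD4T", "TAM"], "sample_id": ["s1", "s2"]}
    )
    cm = CellMap(df)
    with pytest.raises(ValueError, match="s2"):
        bin_composition(np.array([1, 1]), cm, sample_groups={"s1": "high"})


def test_mean_density_nondecreasing_with_bin(rng):
    vals = rng.uniform(size=200)
    cm = make_map(rng.uniform(0, 100, (200, 2)), ["CD4T"] * 200)
    bins = pooled_equal_count_bins(vals, 10)
    table = bin_composition(bins, cm, densities=vals)
    assert (np.diff(table["mean_density"]) >= 0).all()
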