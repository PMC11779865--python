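"""Gaussian kernel density fields and corrected marker-density binning.

The corrected marker density at a location is the ratio of the kernel
density of marker-positive cells to the kernel density of all cells — a
local positive fraction in [0, 1] that is insensitive to overall cellularity.
Per-cell corrected densities are pooled across samples and split into
equal-count bins (default 20) for composition analysis, e.g. the fraction of
T cells and macrophages per corrected-density bin.

Kernels are isotropic Gaussians of bandwidth sigma (µm) with no edge
correction; each point contributes a unit-mass kernel so an intensity field
integrates to the point count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import CellMap

__all__ = [
    "GridSpec",
    "DensityField",
    "kde_field",
    "corrected_density",
    "density_at_cells",
    "pooled_equal_count_bins",
    "bin_composition",
    "per_cell_corrected_density",
]

#: Default KDE bandwidth in µm.
DEFAULT_SIGMA = 500.0
#: Default number of pooled equal-count density bins.
DEFAULT_N_BINS = 20
#: Total-density floor (per µm²) below which the ratio is masked out.
DEFAULT_MIN_TOTAL = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin of node (0,0), spacing, and node counts."""

    origin_x: float
    origin_y: float
    spacing: float
    nx: int
    ny: int

    @classmethod
    def for_points(cls, xy: np.ndarray, sigma: float, spacing: float | None = None, pad_sigmas: float = 4.0):
        """Grid covering the point bounding box padded by ``pad_sigmas``·sigma.

        Default spacing sigma/10 keeps the discrete integral of a kernel
        within 1% of unity.
        """
        xy = np.asarray(xy, dtype=float)
        spacing = sigma / 10.0 if spacing is None else spacing
        pad = pad_sigmas * sigma
        x0, y0 = xy.min(axis=0) - pad
        x1, y1 = xy.max(axis=0) + pad
        nx = int(np.ceil((x1 - x0) / spacing)) + 1
        ny = int(np.ceil((y1 - y0) / spacing)) + 1
        return cls(float(x0), float(y0), spacing, nx, ny)

    @property
    def xs(self) -> np.ndarray:
        return self.origin_x + self.spacing * np.arange(self.nx)

    @property
    def ys(self) -> np.ndarray:
        return self.origin_y + self.spacing * np.arange(self.ny)


@dataclass
class DensityField:
    """Gridded density field; ``values[iy, ix]`` follows image convention."""

    grid: GridSpec
    values: np.ndarray  # (ny, nx)
    sigma: float
    kind: str  # "intensity" | "ratio"
    mask: np.ndarray | None = None  # True where the field is defined (ratio)

    def integral(self) -> float:
        return float(self.values.sum() * self.grid.spacing**2)


def kde_field(points: np.ndarray, sigma: float, grid: GridSpec) -> DensityField:
    """Gaussian KDE intensity field: sum of unit-mass kernels per point.

    value(g) = Σ_i (2πσ²)⁻¹ exp(−‖g−p_i‖² / 2σ²); separable kernels make
    this an (ny×N)·(N×nx) product.  An empty point set yields a zero field.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    ny, nx = grid.ny, grid.nx
    if len(points) == 0:
        import logging

        logging.getLogger("pericuff").warning("kde_field called with empty point set; zero field")
        return DensityField(grid, np.zeros((ny, nx)), sigma, "intensity")
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    gx = np.exp(-((grid.xs[:, None] - points[None, :, 0]) ** 2) * inv2s2)  # (nx, N)
    gy = np.exp(-((grid.ys[:, None] - points[None, :, 1]) ** 2) * inv2s2)  # (ny, N)
    values = (gy @ gx.T) / (2.0 * np.pi * sigma * sigma)
    return DensityField(grid, values, sigma, "intensity")


def corrected_density(
    pos_field: DensityField,
    total_field: DensityField,
    min_total: float = DEFAULT_MIN_TOTAL,
    points: np.ndarray | None = None,
    max_point_distance_sigmas: float = 2.0,
) -> DensityField:
    """Ratio field positive-density / total-density, masked where undefined.

    Nodes with total density below ``min_total`` are masked; when the
    underlying point set is supplied, nodes farther than
    ``max_point_distance_sigmas``·sigma from every point are masked as well
    (the ratio of two vanishing densities is noise, not signal).  Where the
    positive points are a subset of the total points the ratio lies in
    [0, 1]; values are clipped there against floating-point overshoot.
    """
    if pos_field.grid != total_field.grid or pos_field.sigma != total_field.sigma:
        raise ValueError("positive and total fields must share grid and sigma")
    total = total_field.values
    mask = total >= min_total
    if points is not None and len(points) > 0:
        tree = cKDTree(np.asarray(points, dtype=float))
        g = pos_field.grid
        gx, gy = np.meshgrid(g.xs, g.ys)
        d, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
        mask &= (d <= max_point_distance_sigmas * pos_field.sigma).reshape(total.shape)
    values = np.zeros_like(total)
    np.divide(pos_field.values, total, out=values, where=mask)
    np.clip(values, 0.0, 1.0, out=values)
    return DensityField(pos_field.grid, values, pos_field.sigma, "ratio", mask=mask)


def density_at_cells(field: DensityField, cells) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of a field at cell coordinates.

    Returns ``(values, defined)``; cells outside the grid extent or on
    masked nodes get NaN with ``defined`` False — flagged, never silently
    dropped.
    """
    xy = cells.xy if isinstance(cells, CellMap) else np.asarray(cells, dtype=float).reshape(-1, 2)
    g = field.grid
    fx = (xy[:, 0] - g.origin_x) / g.spacing
    fy = (xy[:, 1] - g.origin_y) / g.spacing
    inside = (fx >= 0) & (fx <= g.nx - 1) & (fy >= 0) & (fy <= g.ny - 1)
    values = np.full(len(xy), np.nan)
    defined = inside.copy()
    if inside.any():
        fxi = np.clip(fx[inside], 0, g.nx - 1)
        fyi = np.clip(fy[inside], 0, g.ny - 1)
        ix0 = np.minimum(fxi.astype(int), g.nx - 2) if g.nx > 1 else np.zeros(len(fxi), int)
        iy0 = np.minimum(fyi.astype(int), g.ny - 2) if g.ny > 1 else np.zeros(len(fyi), int)
        tx = fxi - ix0
        ty = fyi - iy0
        v = field.values
        ix1 = np.minimum(ix0 + 1, g.nx - 1)
        iy1 = np.minimum(iy0 + 1, g.ny - 1)
        interp = (
            v[iy0, ix0] * (1 - tx) * (1 - ty)
            + v[iy0, ix1] * tx * (1 - ty)
            + v[iy1, ix0] * (1 - tx) * ty
            + v[iy1, ix1] * tx * ty
        )
        values[inside] = interp
        if field.mask is not None:
            m = field.mask
            ok = m[iy0, ix0] & m[iy0, ix1] & m[iy1, ix0] & m[iy1, ix1]
            sub = np.flatnonzero(inside)
            defined[sub[~ok]] = False
            values[sub[~ok]] = np.nan
    return values, defined


def pooled_equal_count_bins(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Split pooled per-cell densities into equal-count bins, 1 = lowest.

    Cells are sorted by value with ties broken by stable input order and cut
    into ``n_bins`` contiguous groups whose sizes differ by at most one
    (lower bins take the extra cells).  NaN (undefined) values get bin 0 and
    are excluded from the count balance.
    """
    values = np.asarray(values, dtype=float)
    defined = np.flatnonzero(~np.isnan(values))
    if len(defined) < n_bins:
        raise ValueError(f"{len(defined)} defined values < {n_bins} bins")
    order = defined[np.argsort(values[defined], kind="stable")]
    sizes = np.full(n_bins, len(order) // n_bins, dtype=int)
    sizes[: len(order) % n_bins] += 1
    bin_ids = np.zeros(len(values), dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bin_ids[order[start : start + size]] = b
        start += size
    return bin_ids


def bin_composition(
    bin_ids: np.ndarray,
    cells: CellMap,
    phenotypes_of_interest=("CD4T", "CD8T", "TAM"),
    sample_groups: dict[str, str] | None = None,
    densities: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bin composition table.

    One row per (bin, sample group): the group's share of the bin's cells
    and, within that group's cells, the fraction belonging to each phenotype
    of interest.  ``sample_groups`` maps ``sample_id`` to a group label
    (e.g. GTC-high / GTC-low); with no mapping all cells form one group.
    """
    df = cells.df.copy()
    df["bin"] = np.asarray(bin_ids)
    if densities is not None:
        df["density"] = np.asarray(densities)
    df = df[df["bin"] > 0]
    if sample_groups is None:
        df["group"] = "all"
    else:
        unknown = set(df["sample_id"].unique()) - set(sample_groups)
        if unknown:
            raise ValueError(f"sample(s) without group label: {sorted(unknown)}")
        df["group"] = df["sample_id"].map(sample_groups)
    rows = []
    for b, bin_df in df.groupby("bin"):
        n_bin = len(bin_df)
        for grp, grp_df in bin_df.groupby("group"):
            row = {
                "bin": int(b),
                "group": grp,
                "n_cells": len(grp_df),
                "group_fraction": len(grp_df) / n_bin,
            }
            if densities is not None:
                row["mean_density"] = float(grp_df["density"].mean())
            for ph in phenotypes_of_interest:
                row[f"frac_{ph}"] = float((grp_df["phenotype"] == ph).mean())
            rows.append(row)
    out = pd.DataFrame(rows).sort_values(["bin", "group"]).reset_index(drop=True)
    return out


def per_cell_corrected_density(
    cells: CellMap,
    positive_labels,
    sigma: float = DEFAULT_SIGMA,
    spacing: float | None = None,
    min_total: float = DEFAULT_MIN_TOTAL,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected marker density sampled at every cell of one sample.

    Convenience wrapper: builds the positive and total KDE fields on a
    shared grid, forms the masked ratio, and interpolates it back at the
    cell coordinates.  Returns ``(values, defined)``.
    """
    if isinstance(positive_labels, str):
        positive_labels = {positive_labels}
    xy = cells.xy
    if len(xy) == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    grid = GridSpec.for_points(xy, sigma, spacing=spacing)
    pos_xy = cells.of_type(set(positive_labels)).xy
    total = kde_field(xy, sigma, grid)
    pos = kde_field(pos_xy, sigma, grid)
    ratio = corrected_density(pos, total, min_total=min_total, points=xy)
    return density_at_cells(ratio, cells)
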