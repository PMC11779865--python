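"""Synthetic multiplex-IF tissue and expression generator.

Emulates the spatial structures the pipeline quantifies, with known ground
truth: circular vessels wrapped in perivascular membrane annuli,
cuff-confined T cells placed uniformly inside annuli, stromal T cells from
a Thomas cluster process, a gemistocytic tumor-cell (GTC) intensity that
decays with distance from cuff vessels, and tumor-associated macrophages
(TAMs) whose intensity is coupled to the local GTC intensity.  Expression
matrices are negative-binomial counts with an optional planted gene program
(mean multiplied by 2^effect in affected units).

Point processes: homogeneous Poisson for background phenotypes, Thomas
(Poisson parents, Gaussian offspring) for clustered phenotypes, and
inhomogeneous Poisson by thinning for gradient-coupled phenotypes.
Offspring dispersed outside the domain are discarded (no toroidal wrap).
Each generator stage draws from its own substream of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .config import substream
from .core import CellMap, ExpressionMatrix, MembraneHull, ROIFrame

__all__ = [
    "TissueConfig",
    "ExprConfig",
    "simulate_tissue",
    "simulate_roi",
    "simulate_expression",
    "simulate_clustered_labels",
    "simulate_hardcore_labels",
    "simulate_csr_labels",
]

MM2 = 1e-6  # µm² per mm² conversion for intensities given per mm²


@dataclass
class TissueConfig:
    """Parameters of the synthetic tissue generator.

    Intensities are expected cells per mm².  The perivascular annulus
    extends from the vessel wall (``vessel_radius``) to
    ``annulus_outer_radius``; cuff cell density and annulus thickness are
    free parameters of the simulator, not estimates of real tissue.
    """

    width: float = 2000.0
    height: float = 2000.0
    n_vessels: int = 6
    vessel_radius: float = 15.0
    annulus_outer_radius: float = 50.0
    intensities: dict = field(
        default_factory=lambda: {"TumorCell": 1200.0, "BCell": 15.0, "Other": 300.0}
    )
    cuff_t_per_vessel: int = 12
    cuff_vessel_fraction: float = 1.0
    # stromal T cells: Thomas cluster process
    stromal_t_parent_intensity: float = 1.5  # parents per mm²
    stromal_t_offspring: float = 6.0  # mean offspring per parent
    stromal_t_sigma: float = 30.0  # offspring dispersion, µm
    # GTC gradient around cuff vessels
    gtc_peak: float = 800.0  # intensity at the vessel wall
    gtc_floor: float = 100.0  # intensity far from any cuff vessel
    gtc_gradient: float = 150.0  # exponential decay length, µm
    # TAM coupling to local GTC intensity
    tam_baseline: float = 250.0
    tam_coupling: float = 2.0
    cd4_fraction: float = 0.6  # CD4T share of generated T cells
    seed: int = 0

    def __post_init__(self):
        if self.annulus_outer_radius <= self.vessel_radius:
            raise ValueError("annulus outer radius must exceed vessel radius")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be non-negative")

    @property
    def area_mm2(self) -> float:
        return self.width * self.height * MM2


@dataclass
class ExprConfig:
    """Parameters of the synthetic expression generator.

    Counts are negative binomial with gene-level means drawn log-normally
    around ``baseline_mean`` (``gene_mean_log_sd = 0`` gives every gene the
    same mean); ``dispersion`` is the NB size parameter theta
    (var = mu + mu^2/theta; ``inf`` gives Poisson).  The planted program
    multiplies the means of ``program_size`` genes by ``2**effect`` in the
    affected units.
    """

    n_genes: int = 3000
    n_units: int = 200
    baseline_mean: float = 5.0
    dispersion: float = 2.0
    gene_mean_log_sd: float = 1.0
    program_size: int = 50
    effect: float = 1.0  # log2 fold change in affected units
    affected_fraction: float = 0.5
    group_labels: list | None = None  # explicit per-unit affected flags
    seed: int = 0

    def __post_init__(self):
        if self.program_size > self.n_genes:
            raise ValueError("planted program larger than gene universe")
        if not np.isfinite(self.effect):
            raise ValueError("effect size must be finite")


# ---------------------------------------------------------------------------
# point-process primitives

def _poisson_uniform(rng, intensity_mm2, width, height) -> np.ndarray:
    n = rng.poisson(intensity_mm2 * width * height * MM2)
    return np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])


def _thomas(rng, parent_mm2, offspring_mean, sigma, width, height) -> np.ndarray:
    parents = _poisson_uniform(rng, parent_mm2, width, height)
    pts = []
    for px, py in parents:
        k = rng.poisson(offspring_mean)
        if k:
            pts.append(np.column_stack([rng.normal(px, sigma, k), rng.normal(py, sigma, k)]))
    if not pts:
        return np.empty((0, 2))
    xy = np.vstack(pts)
    keep = (xy[:, 0] >= 0) & (xy[:, 0] <= width) & (xy[:, 1] >= 0) & (xy[:, 1] <= height)
    return xy[keep]


def _thin_inhomogeneous(rng, peak_mm2, rate_fn, width, height) -> np.ndarray:
    """Inhomogeneous Poisson by thinning a homogeneous proposal at ``peak_mm2``."""
    if peak_mm2 <= 0:
        return np.empty((0, 2))
    prop = _poisson_uniform(rng, peak_mm2, width, height)
    if len(prop) == 0:
        return prop
    p = rate_fn(prop) / peak_mm2
    return prop[rng.uniform(size=len(prop)) < p]


def _annulus_uniform(rng, cx, cy, r_in, r_out, n) -> np.ndarray:
    u = rng.uniform(size=n)
    r = np.sqrt(u * (r_out**2 - r_in**2) + r_in**2)
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _place_vessels(rng, cfg: TissueConfig) -> np.ndarray:
    """Vessel centers with annuli inside the domain and non-overlapping."""
    margin = cfg.annulus_outer_radius
    min_sep = 2.2 * cfg.annulus_outer_radius
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < cfg.n_vessels and attempts < 10000:
        attempts += 1
        x = rng.uniform(margin, max(cfg.width - margin, margin))
        y = rng.uniform(margin, max(cfg.height - margin, margin))
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
            centers.append((x, y))
    return np.asarray(centers).reshape(-1, 2)


def _t_labels(rng, n, cd4_fraction):
    return np.where(rng.uniform(size=n) < cd4_fraction, "CD4T", "CD8T")


# ---------------------------------------------------------------------------

def simulate_tissue(cfg: TissueConfig):
    """Generate one synthetic tissue sample.

    Returns ``(cell_map, vessels, membranes, truth)`` where ``vessels`` are
    disk hulls (marker CD31), ``membranes`` annular hulls around each vessel
    (marker LAMA2), and ``truth`` is a per-cell array naming the generative
    process (``cuff_t``, ``stromal_t``, ``gtc_gradient``, ``tam``,
    ``background``).  Identical config and seed give identical output.
    """
    rng_v = substream(cfg.seed, "vessels")
    centers = _place_vessels(rng_v, cfg)
    vessels = [
        MembraneHull(Point(cx, cy).buffer(cfg.vessel_radius, quad_segs=32), marker="CD31", hull_id=f"vessel_{i}")
        for i, (cx, cy) in enumerate(centers)
    ]
    membranes = [
        MembraneHull(
            Point(cx, cy).buffer(cfg.annulus_outer_radius, quad_segs=32)
            .difference(Point(cx, cy).buffer(cfg.vessel_radius, quad_segs=32)),
            marker="LAMA2",
            hull_id=f"annulus_{i}",
        )
        for i, (cx, cy) in enumerate(centers)
    ]

    n_cuff_vessels = int(round(cfg.cuff_vessel_fraction * len(centers)))
    cuff_centers = centers[:n_cuff_vessels]

    xs, ys, phen, proc = [], [], [], []

    def add(xy, labels, process):
        if len(xy) == 0:
            return
        xs.append(xy[:, 0])
        ys.append(xy[:, 1])
        phen.append(np.asarray(labels, dtype=object))
        proc.append(np.full(len(xy), process, dtype=object))

    # cuff T cells: uniform inside each cuff vessel's annulus
    rng_c = substream(cfg.seed, "cuff_t")
    for cx, cy in cuff_centers:
        # keep strictly off the annulus boundary so containment is unambiguous
        xy = _annulus_uniform(
            rng_c, cx, cy, cfg.vessel_radius + 0.5, cfg.annulus_outer_radius - 0.5, cfg.cuff_t_per_vessel
        )
        add(xy, _t_labels(rng_c, len(xy), cfg.cd4_fraction), "cuff_t")

    # stromal T cells: Thomas clusters over the whole domain
    rng_s = substream(cfg.seed, "stromal_t")
    xy = _thomas(
        rng_s, cfg.stromal_t_parent_intensity, cfg.stromal_t_offspring,
        cfg.stromal_t_sigma, cfg.width, cfg.height,
    )
    add(xy, _t_labels(rng_s, len(xy), cfg.cd4_fraction), "stromal_t")

    # distance from a point to the nearest cuff vessel wall
    def wall_distance(xy):
        if len(cuff_centers) == 0:
            return np.full(len(xy), np.inf)
        d = np.sqrt(((xy[:, None, :] - cuff_centers[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        return np.maximum(d - cfg.vessel_radius, 0.0)

    def gtc_rate(xy):
        g = np.exp(-wall_distance(xy) / cfg.gtc_gradient)
        return cfg.gtc_floor + (cfg.gtc_peak - cfg.gtc_floor) * g

    rng_g = substream(cfg.seed, "gtc")
    peak = max(cfg.gtc_peak, cfg.gtc_floor)
    add_xy = _thin_inhomogeneous(rng_g, peak, gtc_rate, cfg.width, cfg.height)
    add(add_xy, ["GTC"] * len(add_xy), "gtc_gradient")

    # TAMs: baseline intensity modulated by the normalized local GTC signal
    rng_t = substream(cfg.seed, "tam")
    def tam_rate(xy):
        g = np.exp(-wall_distance(xy) / cfg.gtc_gradient)
        if not np.isfinite(g).all():
            g = np.zeros(len(xy))
        return cfg.tam_baseline * (1.0 + cfg.tam_coupling * g)

    tam_peak = cfg.tam_baseline * (1.0 + max(cfg.tam_coupling, 0.0))
    xy = _thin_inhomogeneous(rng_t, tam_peak, tam_rate, cfg.width, cfg.height)
    add(xy, ["TAM"] * len(xy), "tam")

    # homogeneous background phenotypes
    rng_b = substream(cfg.seed, "background")
    for label in sorted(cfg.intensities):
        xy = _poisson_uniform(rng_b, cfg.intensities[label], cfg.width, cfg.height)
        add(xy, [label] * len(xy), "background")

    if xs:
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(sum(len(a) for a in xs))],
                "x": np.concatenate(xs),
                "y": np.concatenate(ys),
                "phenotype": np.concatenate(phen),
                "sample_id": f"sim_{cfg.seed}",
                "roi_id": None,
            }
        )
        truth = np.concatenate(proc)
    else:
        df = pd.DataFrame(columns=list(CellMap.COLUMNS))
        truth = np.empty(0, dtype=object)
    cell_map = CellMap(df, provenance={"generator": "simulate_tissue", "seed": cfg.seed})
    return cell_map, vessels, membranes, truth


def simulate_roi(cfg: TissueConfig, phenotype: str):
    """Generate one ROI-sized field (670 x 502 µm) of a given tissue phenotype.

    ``cuff``: at least one vessel with a populated annulus; ``stromal_T``:
    T cells present but none inside any annulus; ``absent``: no T cells.
    Returns ``(cell_map, vessels, membranes, frame, truth)``.
    """
    if phenotype not in ("cuff", "stromal_T", "absent"):
        raise ValueError(f"unknown ROI phenotype {phenotype!r}")
    frame = ROIFrame(0.0, 0.0, tissue_phenotype=phenotype)
    roi_cfg = replace(
        cfg,
        width=frame.width,
        height=frame.height,
        n_vessels=min(cfg.n_vessels, 2),
    )
    if phenotype == "cuff":
        roi_cfg = replace(roi_cfg, cuff_t_per_vessel=max(cfg.cuff_t_per_vessel, 3))
    else:
        roi_cfg = replace(roi_cfg, cuff_t_per_vessel=0)
    if phenotype == "absent":
        roi_cfg = replace(roi_cfg, stromal_t_parent_intensity=0.0)

    cell_map, vessels, membranes, truth = simulate_tissue(roi_cfg)

    if phenotype == "stromal_T":
        # evict T cells that landed inside an annulus so no cuff can form,
        # and guarantee at least one stromal T cell remains
        from .geometry import assign_cells_to_hulls

        t_mask = np.isin(cell_map.phenotypes, ["CD4T", "CD8T"])
        assigned = assign_cells_to_hulls(cell_map, membranes)
        drop = t_mask & (assigned >= 0)
        keep = ~drop
        cell_map = cell_map.subset(keep)
        truth = truth[keep]
        if not np.isin(cell_map.phenotypes, ["CD4T", "CD8T"]).any():
            rng = substream(cfg.seed, "stromal_rescue")
            extra = pd.DataFrame(
                {
                    "cell_id": ["t_rescue_0"],
                    "x": [rng.uniform(0, frame.width)],
                    "y": [rng.uniform(0, frame.height)],
                    "phenotype": ["CD4T"],
                    "sample_id": cell_map.df["sample_id"].iloc[0] if len(cell_map) else f"sim_{cfg.seed}",
                    "roi_id": None,
                }
            )
            # re-draw until the rescue cell is outside every annulus
            while any(m.contains_point(extra.x[0], extra.y[0]) for m in membranes):
                extra.loc[0, "x"] = rng.uniform(0, frame.width)
                extra.loc[0, "y"] = rng.uniform(0, frame.height)
            cell_map = CellMap(pd.concat([cell_map.df, extra], ignore_index=True), cell_map.provenance)
            truth = np.concatenate([truth, ["stromal_t"]])
    return cell_map, vessels, membranes, frame, truth


def simulate_expression(cfg: ExprConfig):
    """Generate a negative-binomial count matrix with a planted gene program.

    Returns ``(matrix, truth)`` where ``truth`` holds the planted gene ids
    and the affected unit ids.  With ``dispersion = inf`` counts are Poisson.
    """
    rng = substream(cfg.seed, "expression")
    genes = [f"g{i}" for i in range(cfg.n_genes)]
    units = [f"u{i}" for i in range(cfg.n_units)]
    log_sd = cfg.gene_mean_log_sd
    if log_sd > 0:
        gene_means = cfg.baseline_mean * np.exp(rng.normal(0.0, log_sd, cfg.n_genes) - log_sd**2 / 2.0)
    else:
        gene_means = np.full(cfg.n_genes, cfg.baseline_mean)

    planted = rng.choice(cfg.n_genes, size=cfg.program_size, replace=False)
    if cfg.group_labels is not None:
        affected = np.asarray(cfg.group_labels, dtype=bool)
        if len(affected) != cfg.n_units:
            raise ValueError("group_labels length must equal n_units")
    else:
        n_aff = int(round(cfg.affected_fraction * cfg.n_units))
        affected = np.zeros(cfg.n_units, dtype=bool)
        affected[rng.choice(cfg.n_units, size=n_aff, replace=False)] = True

    mu = np.tile(gene_means[:, None], (1, cfg.n_units))
    if cfg.effect != 0.0:
        mu[np.ix_(planted, np.flatnonzero(affected))] *= 2.0**cfg.effect

    if np.isinf(cfg.dispersion):
        counts = rng.poisson(mu)
    else:
        theta = cfg.dispersion
        counts = rng.negative_binomial(theta, theta / (theta + mu))
    matrix = ExpressionMatrix(counts.astype(float), genes, units, value_kind="raw_count")
    truth = {
        "planted_genes": [genes[i] for i in sorted(planted)],
        "affected_units": [units[i] for i in np.flatnonzero(affected)],
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# labeled point patterns with planted spatial structure
#
# Single-purpose generators for calibrating the permutation z-score: a CSR
# null (labels carry no spatial information), attractive clustering (Thomas
# offspring of one label over a uniform background) and repulsion (hard-core
# minimum separation of one label over a uniform background).

def _label_map(xy: np.ndarray, labels: np.ndarray, seed) -> CellMap:
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(xy))],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "phenotype": labels,
            "sample_id": f"sim_{seed}",
            "roi_id": None,
        }
    )
    return CellMap(df, provenance={"generator": "labeled_pattern", "seed": seed})


def simulate_csr_labels(seed, n_cells=500, n_labeled=250, label="T", background_label="Other",
                        width=1000.0, height=1000.0) -> CellMap:
    """CSR points with labels assigned completely at random (the calibration null)."""
    rng = substream(seed, "csr_labels")
    xy = np.column_stack([rng.uniform(0, width, n_cells), rng.uniform(0, height, n_cells)])
    labels = np.array([label] * n_labeled + [background_label] * (n_cells - n_labeled), dtype=object)
    return _label_map(xy, labels[rng.permutation(n_cells)], seed)


def simulate_clustered_labels(seed, label="T", background_label="Other", width=1000.0, height=1000.0,
                              n_background=400, n_parents=5, offspring_mean=10.0, sigma=25.0) -> CellMap:
    """Thomas-clustered labeled cells over a uniform background.

    The labeled cells are offspring of Poisson-thinned parents, so their
    within-type nearest-neighbor distances are short relative to a random
    relabeling of the whole map (expected z < 0).
    """
    rng = substream(seed, "clustered_labels")
    bg = np.column_stack([rng.uniform(0, width, n_background), rng.uniform(0, height, n_background)])
    pts = [bg]
    n_lab = 0
    parents = np.column_stack([rng.uniform(0, width, n_parents), rng.uniform(0, height, n_parents)])
    for px, py in parents:
        k = rng.poisson(offspring_mean)
        if k:
            xy = np.column_stack([rng.normal(px, sigma, k), rng.normal(py, sigma, k)])
            keep = (xy[:, 0] >= 0) & (xy[:, 0] <= width) & (xy[:, 1] >= 0) & (xy[:, 1] <= height)
            pts.append(xy[keep])
            n_lab += int(keep.sum())
    xy = np.vstack(pts)
    labels = np.array([background_label] * n_background + [label] * n_lab, dtype=object)
    return _label_map(xy, labels, seed)


def simulate_hardcore_labels(seed, label="T", background_label="Other", width=1000.0, height=1000.0,
                             n_background=400, n_labeled=50, min_distance=70.0) -> CellMap:
    """Hard-core labeled cells (pairwise separation >= min_distance) over a background.

    The labeled cells repel each other, so their within-type
    nearest-neighbor distances exceed those of a random relabeling
    (expected z > 0).
    """
    rng = substream(seed, "hardcore_labels")
    bg = np.column_stack([rng.uniform(0, width, n_background), rng.uniform(0, height, n_background)])
    placed: list = []
    attempts = 0
    while len(placed) < n_labeled and attempts < 200000:
        attempts += 1
        c = rng.uniform(0, [width, height])
        if not placed or np.sqrt(((np.asarray(placed) - c) ** 2).sum(axis=1)).min() >= min_distance:
            placed.append(c)
    lab_xy = np.asarray(placed).reshape(-1, 2)
    xy = np.vstack([bg, lab_xy])
    labels = np.array([background_label] * n_background + [label] * len(lab_xy), dtype=object)
    return _label_map(xy, labels, seed)
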