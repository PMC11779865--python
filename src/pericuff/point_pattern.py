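"""Nearest-neighbor distance statistics and permutation-null z-scores.

The central statistic is the inter-cell distance z-score: for a
(from-type, to-type) phenotype pair, the observed mean nearest-neighbor
distance is compared with a null distribution obtained by randomly
reassigning phenotype labels over all cells of the map (marginal label
counts preserved).  Negative z means the from-type cells sit closer to the
to-type cells than random labeling would produce (clustering); positive z
means dispersion.

Two null modes are provided: ``sampled`` draws ``n_perm`` random label
assignments (with replacement from the assignment space; the observed
labeling is not added to the null, since the statistic reported is a
z-score, not a permutation p-value), and ``exhaustive`` enumerates every
distinct assignment of the label multiset, which is feasible for small maps
and is seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.stats import ks_2samp

from .core import CellMap, MembraneHull

__all__ = [
    "NNZResult",
    "KSResult",
    "UndefinedStatisticError",
    "nn_distances",
    "permutation_nn_z",
    "zscore_matrix",
    "vessel_distance_ks",
]

# Above this many cells the dense pairwise-distance path is abandoned for a
# per-permutation KD-tree (memory, not speed, is the constraint).
_DENSE_LIMIT = 4000


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on this input (e.g. empty to-set)."""


@dataclass
class NNZResult:
    """Permutation nearest-neighbor z-score for one phenotype pair."""

    from_type: str
    to_type: str
    n_from: int
    n_to: int
    observed_mean_nn: float
    null_mean: float
    null_sd: float
    z: float
    n_perm: int
    mode: str
    undefined: bool = False
    reason: str = ""


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of vessel-distance distributions."""

    D: float
    p_value: float
    n_pos: int
    n_neg: int
    median_pos: float
    median_neg: float


def nn_distances(from_cells: CellMap, to_cells: CellMap, exclude_self: bool = False) -> np.ndarray:
    """Distance from each from-cell to its nearest to-cell, in µm.

    With ``exclude_self``, a from-cell present in the to-set (same
    ``cell_id``) is not its own neighbor; distinct cells at identical
    coordinates still count, at distance 0.
    """
    if len(from_cells) == 0:
        return np.empty(0)
    to_xy = to_cells.xy
    from_xy = from_cells.xy
    if exclude_self:
        to_ids = {cid: i for i, cid in enumerate(to_cells.df["cell_id"])}
        self_idx = np.array(
            [to_ids.get(cid, -1) for cid in from_cells.df["cell_id"]], dtype=int
        )
        n_eff = len(to_cells) - 1 if (self_idx >= 0).any() else len(to_cells)
    else:
        self_idx = np.full(len(from_cells), -1, dtype=int)
        n_eff = len(to_cells)
    if n_eff < 1:
        raise UndefinedStatisticError("to-set empty after self-exclusion")
    tree = cKDTree(to_xy)
    d, idx = tree.query(from_xy, k=min(2, len(to_cells)))
    if d.ndim == 1:
        d, idx = d[:, None], idx[:, None]
    take_second = (self_idx >= 0) & (idx[:, 0] == self_idx)
    out = np.where(take_second, d[:, -1], d[:, 0])
    return out.astype(float)


def _mean_nn_from_dense(D: np.ndarray, from_idx: np.ndarray, to_idx: np.ndarray, same_type: bool) -> float:
    sub = D[np.ix_(from_idx, to_idx)]
    if same_type:
        sub = sub.copy()
        np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _mean_nn_from_tree(xy: np.ndarray, from_idx: np.ndarray, to_idx: np.ndarray, same_type: bool) -> float:
    tree = cKDTree(xy[to_idx])
    k = 2 if same_type else 1
    d, idx = tree.query(xy[from_idx], k=min(k, len(to_idx)))
    if k == 1 or d.ndim == 1:
        return float(np.atleast_1d(d).mean())
    # within-type: column 0 is the self match (distance 0 to itself)
    self_pos = np.arange(len(from_idx))
    take_second = idx[:, 0] == self_pos
    return float(np.where(take_second, d[:, -1], d[:, 0]).mean())


def _enumerate_assignments(labels: np.ndarray) -> Iterable[np.ndarray]:
    from sympy.utilities.iterables import multiset_permutations

    for perm in multiset_permutations(list(labels)):
        yield np.asarray(perm)


def permutation_nn_z(
    cell_map: CellMap,
    from_type: str,
    to_type: str,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "sampled",
) -> NNZResult:
    """Permutation nearest-neighbor z-score for one phenotype pair.

    The null reassigns labels over all cells of the map (all phenotypes
    jointly, preserving marginal counts) and recomputes the mean NN distance
    for each assignment.  ``z = (observed - null_mean) / null_sd``; when the
    null is degenerate (``null_sd == 0``) the result is flagged undefined
    rather than silently reported as 0.

    ``mode='exhaustive'`` enumerates all distinct label assignments (use on
    small maps only); its null moments use the population variance, whereas
    sampled mode uses the ddof=1 sample variance.
    """
    labels = cell_map.phenotypes
    n_from = int((labels == from_type).sum())
    n_to = int((labels == to_type).sum())
    same = from_type == to_type
    if n_from == 0:
        raise UndefinedStatisticError(f"no cells of from-type {from_type!r} in map")
    if n_to == 0:
        raise UndefinedStatisticError(f"no cells of to-type {to_type!r} in map")
    if same and n_to < 2:
        raise UndefinedStatisticError(
            f"within-type statistic for {from_type!r} needs >=2 cells, found {n_to}"
        )
    if mode not in ("sampled", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "sampled" and n_perm < 2:
        raise ValueError("sampled mode requires n_perm >= 2")

    xy = cell_map.xy
    n = len(cell_map)
    dense = n <= _DENSE_LIMIT
    D = cdist(xy, xy) if dense else None

    def stat(lab: np.ndarray) -> float:
        fi = np.flatnonzero(lab == from_type)
        ti = fi if same else np.flatnonzero(lab == to_type)
        if dense:
            return _mean_nn_from_dense(D, fi, ti, same)
        return _mean_nn_from_tree(xy, fi, ti, same)

    observed = stat(labels)

    if mode == "exhaustive":
        null = np.array([stat(lab) for lab in _enumerate_assignments(labels)])
        null_mean = float(null.mean())
        null_sd = float(null.std(ddof=0))
        n_used = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for p in range(n_perm):
            null[p] = stat(labels[rng.permutation(n)])
        null_mean = float(null.mean())
        null_sd = float(null.std(ddof=1))
        n_used = n_perm

    if null_sd == 0.0:
        return NNZResult(
            from_type, to_type, n_from, n_to, observed, null_mean, 0.0,
            float("nan"), n_used, mode, undefined=True, reason="degenerate null (sd = 0)",
        )
    z = (observed - null_mean) / null_sd
    return NNZResult(from_type, to_type, n_from, n_to, observed, null_mean, null_sd, z, n_used, mode)


def zscore_matrix(
    cell_map: CellMap,
    type_pairs: Sequence[tuple[str, str]],
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "sampled",
) -> pd.DataFrame:
    """Table of z-scores for a list of (from, to) phenotype pairs.

    Pairs whose types are missing from the map are emitted as undefined
    rows (not dropped), so downstream tables keep one row per requested
    pair.
    """
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(type_pairs))
    for (ft, tt), child in zip(type_pairs, ss):
        try:
            res = permutation_nn_z(
                cell_map, ft, tt, n_perm=n_perm,
                seed=child.generate_state(1)[0] if seed is not None else None,
                mode=mode,
            )
        except UndefinedStatisticError as exc:
            labels = cell_map.phenotypes
            res = NNZResult(
                ft, tt, int((labels == ft).sum()), int((labels == tt).sum()),
                float("nan"), float("nan"), float("nan"), float("nan"),
                0, mode, undefined=True, reason=str(exc),
            )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def vessel_distance_ks(
    cell_map: CellMap,
    vessels: Sequence[MembraneHull],
    positive_label: str | Sequence[str],
    max_per_group: int = 2000,
    seed: int | None = None,
) -> KSResult:
    """Compare distance-to-nearest-vessel between marker-positive and negative cells.

    Distance is the Euclidean distance from the cell centroid to the nearest
    point of any vessel polygon (0 inside a vessel).  Each group is
    independently subsampled without replacement to ``max_per_group`` cells
    before a two-sided two-sample Kolmogorov-Smirnov test.
    """
    if len(vessels) == 0:
        raise ValueError("no vessel polygons supplied")
    if isinstance(positive_label, str):
        positive_label = {positive_label}
    pos_mask = cell_map.df["phenotype"].isin(set(positive_label)).to_numpy()
    if pos_mask.sum() == 0 or (~pos_mask).sum() == 0:
        raise UndefinedStatisticError("both positive and negative groups must be non-empty")

    from shapely import distance as shp_distance
    from shapely.geometry import Point
    from shapely.strtree import STRtree

    geoms = [v.polygon for v in vessels]
    tree = STRtree(geoms)
    points = [Point(x, y) for x, y in cell_map.xy]
    nearest = tree.nearest(points)
    dists = np.array([shp_distance(points[i], geoms[j]) for i, j in enumerate(np.atleast_1d(nearest))])

    rng = np.random.default_rng(seed)
    groups = {}
    for name, mask in (("pos", pos_mask), ("neg", ~pos_mask)):
        d = dists[mask]
        if len(d) > max_per_group:
            d = d[rng.choice(len(d), size=max_per_group, replace=False)]
        groups[name] = d
    ks = ks_2samp(groups["pos"], groups["neg"], alternative="two-sided")
    return KSResult(
        D=float(ks.statistic),
        p_value=float(ks.pvalue),
        n_pos=len(groups["pos"]),
        n_neg=len(groups["neg"]),
        median_pos=float(np.median(groups["pos"])),
        median_neg=float(np.median(groups["neg"])),
    )
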