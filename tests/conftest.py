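import itertools

import numpy as np
import pandas as pd
import pytest

from pericuff import CellMap


def make_map(xy, labels, ids=None) -> CellMap:
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=object)
    if ids is None:
        ids = [f"c{i}" for i in range(len(xy))]
    return CellMap(
        pd.DataFrame({"cell_id": ids, "x": xy[:, 0], "y": xy[:, 1], "phenotype": labels})
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# independent oracles shared by unit and acceptance tests

def brute_nn_mean(xy, from_idx, to_idx, exclude_self):
    """O(n^2) mean nearest-neighbor distance, plain loops, no trees."""
    dists = []
    for i in from_idx:
        best = np.inf
        for j in to_idx:
            if exclude_self and i == j:
                continue
            d = float(np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]))
            if d < best:
                best = d
        dists.append(best)
    return float(np.mean(dists))


def enumerate_null(xy, labels, from_type, to_type):
    """Null mean/sd of the mean-NN statistic over every distinct label assignment.

    Enumerates assignments by choosing index sets per label with
    itertools.combinations (independent of the implementation's
    multiset-permutation path) and computes each statistic by brute force.
    """
    labels = np.asarray(labels)
    n = len(labels)
    kinds, counts = np.unique(labels, return_counts=True)
    same = from_type == to_type
    stats = []

    def recurse(remaining, kind_i, assign):
        if kind_i == len(kinds):
            lab = np.empty(n, dtype=object)
            for k, idxs in assign.items():
                lab[list(idxs)] = k
            fi = [i for i in range(n) if lab[i] == from_type]
            ti = fi if same else [i for i in range(n) if lab[i] == to_type]
            stats.append(brute_nn_mean(xy, fi, ti, exclude_self=same))
            return
        k = kinds[kind_i]
        for combo in itertools.combinations(sorted(remaining), counts[kind_i]):
            assign[k] = combo
            recurse(remaining - set(combo), kind_i + 1, assign)
            del assign[k]

    recurse(set(range(n)), 0, {})
    arr = np.asarray(stats)
    return float(arr.mean()), float(arr.std(ddof=0)), len(arr)


def raycast_contains(poly_xy, holes, x, y):
    """Even-odd point-in-polygon by ray casting (boundary not special-cased)."""

    def crossings(ring, x, y):
        c = 0
        for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
            if (y1 > y) != (y2 > y):
                xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if xi > x:
                    c += 1
        return c

    total = crossings(poly_xy, x, y)
    for h in holes:
        total += crossings(h, x, y)
    return total % 2 == 1
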