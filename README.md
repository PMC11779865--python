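# pericuff

Spatial quantification of perivascular immune niches in phenotyped tissue
maps. In IDH-mutant astrocytoma, T cells are largely confined to
perivascular cuffs — aggregates trapped between the endothelial and
parenchymal (LAMA2⁺) basement membranes — surrounded by gemistocytic tumor
cells (GTCs) and tumor-associated macrophages (TAMs). `pericuff`
implements the statistics needed to quantify this architecture from
multiplex-immunofluorescence exports (cell tables + polygon annotations),
together with a synthetic tissue generator so every stage is testable with
known ground truth.

Intended users: computational biologists analysing phenotyped cell
coordinates from whole-slide or ROI-based multiplex imaging, with or
without matched expression data.

## What it computes

**Inter-cell distance z-score.** For a phenotype pair (A → B), the observed
mean nearest-neighbor distance d̄ is compared with a permutation null built
by randomly reassigning all phenotype labels over the cells of the map
(marginal counts preserved; 1000 reassignments per ROI, 100 per whole
slide, or exhaustive enumeration on small maps):

    z = (d̄_obs − μ_null) / σ_null

Negative z = clustering (A sits closer to B than chance), positive z =
dispersion. Degenerate nulls (σ = 0) are flagged, never reported as 0.

**T-cell cuffs.** Membrane polygons (GeoJSON) become closed hulls
(morphological closing with a µm-scale smoothing radius); a hull containing
more than 2 T-cell centroids (even–odd containment, boundary inclusive,
nested hulls resolved to smallest area) is a cuff, reported with area,
equivalent radius √(area/π) and size class. Distances from cells to the
nearest CD31⁺ vessel are compared between marker-positive and negative
cells by a two-sample KS test with capped subsampling (default 2000 per
group).

**Corrected marker density.** Ratio of the Gaussian KDE (bandwidth σ,
default 500 µm) of marker-positive cells to the KDE of all cells — a local
positive fraction in [0, 1]. Per-cell values are pooled across samples into
20 equal-count bins and bin composition (group share, phenotype fractions)
is tabulated.

**Bin-matched enrichment score.** For a gene set G, genes are ranked by mean
expression into 30 equal-count bins; each gene of G draws 100 background
genes from its own bin (R = 100×|G|), and the per-unit score is
mean(G) − mean(R), removing mean-expression bias.

**GTC scoring.** Four-bin abundance category (−, +, ++, +++ at 0 / 20 / 40 %)
and the ~20 % high/low dichotomy; pseudo-count log transforms for per-ROI
counts; rank-sum / KS / chi-square group comparisons with
Benjamini–Hochberg adjustment.

## Worked example

```python
import pericuff as pc

# synthetic 2 x 2 mm sample: 6 vessels with annular membranes, cuff T cells,
# a GTC gradient around vessels and GTC-coupled TAMs
cells, vessels, membranes, truth = pc.simulate_tissue(pc.TissueConfig(seed=3))
print(len(cells), "cells,", len(vessels), "vessels")

cuffs = pc.detect_cuffs(cells, membranes)
print(len(cuffs), "cuffs, T-cell counts", [c.t_cell_count for c in cuffs])

roi, v, m, frame, t = pc.simulate_roi(pc.TissueConfig(seed=5), "cuff")
res = pc.permutation_nn_z(roi, "CD4T", "CD4T", n_perm=200, seed=1)
print("within-CD4T z:", round(res.z, 2))
```

prints

```
8298 cells, 6 vessels
6 cuffs, T-cell counts [12, 12, 12, 12, 12, 12]
within-CD4T z: -4.45
```

— every simulated vessel carries a detected cuff, and the within-type
z-score of the cuff ROI is strongly negative: the T cells are clustered far
beyond what random labeling of the same cell positions produces.

The same analyses run from the shell via the `pericuff` CLI
(`simulate`, `zscore`, `cuffs`, `vessel-ks`, `density`, `score`, `gtc-bin`,
`register`, `run-roi`, `run-wholeslide`); each run writes tidy TSVs plus a
JSON metadata record (seed, config hash, input checksums).

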