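# Methods

## The statistics

### Permutation nearest-neighbor z-score

For a phenotyped point set (one map = one ROI or one whole sample) and an
ordered phenotype pair (A → B), the statistic is the mean over A-cells of
the distance to the nearest B-cell. The null reassigns the *complete* label
vector over all cell positions — all phenotypes jointly, preserving
marginal counts — and recomputes the statistic per reassignment;
z = (observed − null mean)/null sd. Scoping the permutation to the whole
field (rather than to the two phenotypes involved) is a deliberate choice:
it asks "are A-labels placed on positions unusually close to B-labels,
given where all cells sit", which is the question the tissue-architecture
analysis poses.

Conventions worth stating because they are easy to get silently wrong:

- Within-type pairs (A → A) exclude the cell itself but count distinct
  coincident cells at distance 0.
- Sampled mode draws label assignments uniformly with replacement from the
  assignment space and does **not** add the observed labeling to the null:
  the reported quantity is a z-score, not a permutation p-value, so the
  +1 correction customary for p-values does not apply.
- Exhaustive mode enumerates every distinct assignment of the label
  multiset (feasible up to ~10 cells) and is seed-free; its null moments
  use the population variance (ddof 0), sampled mode the ddof-1 estimator.
- A degenerate null (sd = 0, e.g. a single-phenotype map) flags the result
  undefined; it is never reported as z = 0.
- Defaults: 1000 permutations in ROI mode, 100 in whole-slide mode.

Calibration behavior (verified by the test suite): with labels assigned at
random on CSR points the z distribution is centered (|mean| < 0.15) with
near-nominal tails; Thomas-clustered labels over a uniform background give
z < 0 and hard-core labels z > 0, essentially always at the simulated
effect sizes.

### Cuff geometry

Membrane polygons are smoothed/merged by morphological closing — buffer
out, union, buffer in, with a smoothing radius in µm (default 10) —
followed by light vertex simplification. This replaces external
concave-hull routines with an operation that is unit-interpretable and
testable against a raster oracle. Because the polygonal approximation of
buffer arcs can erode convex corners by ~10⁻³ relative area, each output
part is unioned with the inputs it covers, making "input ⊆ output" exact.

Containment is even-odd point-in-polygon of the cell centroid with
inclusive boundaries; a centroid inside the lumen hole of an annulus is
*not* in the annulus; nested containing hulls resolve to the smallest area
(deterministic tie-break). A cuff is a hull with ≥ 3 contained T cells;
its equivalent radius is √(area/π) (the "cuff radius" definition here —
one of several possible conventions), with size classes small/medium/large
at configurable cutoffs (defaults 50/100 µm — package defaults to be
tuned per cohort, not biological constants).

ROI tissue phenotype: `cuff` if ≥ 1 detected cuff, else `stromal_T` if
≥ 1 T cell, else `absent`.

Outline registration for consecutive sections is a brute-force grid search
(rotation about the moving outline's centroid × translations) maximizing
IoU; the grid contains the identity, so aligned IoU never drops below the
unaligned value. Defaults ±15° in 0.5° steps and ±500 µm in 25 µm steps;
the consensus outline is the geometric intersection of the aligned
outlines. Grid search is exact on the grid, at the cost of runtime that
grows with grid size — analyses in this repository use coarser grids sized
to their synthetic inputs.

### Corrected marker density

Each point contributes a unit-mass isotropic Gaussian of bandwidth σ, so an
intensity field integrates to the point count (no edge correction). The
corrected density is positive-KDE / total-KDE, a local positive fraction in
[0, 1] wherever positives ⊆ totals. σ defaults to 500 µm, a whole-slide
scale bandwidth; slide-analysis toolchains sometimes express the same
bandwidth in pixels (250 µm at 0.5 µm/px), so σ is an explicit config
parameter everywhere — and because the ratio is scale-equivariant, the
choice rescales the field's resolution, not its values. The synthetic
whole-slide pipeline defaults to σ = 150 µm because its samples are 2 mm
across, not centimetres.

Grid spacing defaults to σ/10 with the bounding box padded by 4σ (< 1 %
integration error). The ratio is masked where total density < 10⁻¹² µm⁻²
or farther than 2σ from every point: a ratio of two vanishing densities is
noise. Per-cell values come from bilinear interpolation; cells on masked
nodes or outside the grid are flagged, not dropped. Pooling across samples
uses each sample's own fields (per-sample KDE, then pooled per-cell
values), then splits the pooled values into 20 equal-count bins — sorted by
value, ties broken by stable input order, sizes differing by ≤ 1 with the
extra cells in the lowest bins, bin 1 = lowest density.

### Bin-matched enrichment score

Genes are ranked by mean expression across units and cut into 30
equal-count bins (stable ties). For each gene of the query set G, 100
background genes are drawn from that gene's bin — without replacement
within one target's draws when the bin is large enough, else with
replacement (flagged) so small bins cannot deadlock; a gene may serve
several targets. Score per unit = mean expression of G − mean of the
background multiset R (|R| = 100·|G|). An exhaustive option uses each
target's entire bin, removing sampling noise. Scores are computed on the
matrix as given (normalized input expected); no normalization is performed
here.

A property of this estimator worth knowing: if a planted program shifts G
by Δ in a fraction f of units, binning sees the inflated overall means, the
matched background sits ≈ f·Δ higher, and the group means land at
≈ (1−f)·Δ and −f·Δ. The *difference* between affected and unaffected units
recovers Δ; the locations are biased toward zero symmetrically. The test
suite asserts both facts, and the recovery benchmark uses f = 0.1 where
absolute thresholding is meaningful.

### GTC scoring and comparisons

The four-bin GTC abundance category uses right-closed bins — 0 → "−",
(0, 0.2] → "+", (0.2, 0.4] → "++", > 0.4 → "+++" — because histology
interval labels like "0–20 % / 20–40 %" overlap at their edges and a
deterministic convention is required; the binary class is high iff
fraction > 0.20 (strict). Counts per
ROI are log-transformed after adding a pseudo-count (default 1, natural
log). Group comparisons are two-sided (rank-sum exact in small samples via
scipy, KS, chi-square) with Benjamini–Hochberg adjustment across the
declared family; degenerate contrasts are flagged rows, excluded from the
family.

## The synthetic generator

`simulate_tissue` emulates the structures the pipeline quantifies, not the
imaging process: vessels are non-overlapping disks (radius 15 µm) wrapped
in annular membranes (outer radius 50 µm); cuff T cells are placed
uniformly inside annuli (12 per vessel, 0.5 µm inside the boundary so
containment is unambiguous); stromal T cells follow a Thomas process
(parents 1.5 /mm², mean 6 offspring, σ 30 µm); GTC intensity is an
inhomogeneous Poisson field λ(x) = floor + (peak − floor)·exp(−d/L) with
d the distance to the nearest cuff-vessel wall (peak 800, floor 100 /mm²,
L = 150 µm), realized by thinning; TAM intensity is
baseline·(1 + coupling·exp(−d/L)) (baseline 250 /mm², coupling 2);
background phenotypes are homogeneous Poisson (tumor 1200, other 300,
B cells 15 /mm²). Offspring dispersed outside the domain are discarded (a
small, accepted edge bias mirroring finite sections). Each stage draws from
its own named substream of the master seed, so one stage's output is stable
under changes to another's config. Cuff density and annulus thickness are
free parameters chosen to give realistic cuff sizes at this domain
scale; they are simulator settings, not tissue measurements.

`simulate_roi` produces a 670 × 502 µm frame (the standard ROI geometry
of VECTRA-style multiplex imaging at 0.5 µm/px) of declared tissue
phenotype: `cuff` guarantees a populated annulus, `stromal_T` evicts any
T cell that lands inside an annulus (and guarantees at least one stromal
T cell), `absent` has none.

`simulate_expression` draws negative-binomial counts with gene means
log-normal around a baseline (default mean 5, log-sd 1, NB size θ = 2;
θ = ∞ gives Poisson) and multiplies a planted program's means by 2^effect
in the affected units.

What the generator does **not** emulate — staining artifacts,
autofluorescence, segmentation error, irregular vessel shapes, 3-D
structure, cell-size exclusion effects — bounds what passing tests show:
the pipeline is correct on data satisfying its model assumptions; real
tissue adds noise sources the suite does not probe.

## Problem sizes and numerical choices

Test and acceptance runs use cohort sizes chosen to make every property
measurable with comfortable margins on a single CPU: 50 maps for
exhaustive-null verification (5–8 cells, where enumeration is exact), 200
replicates × 500 permutations for CSR calibration, 100 simulations each for
the clustering/repulsion sign checks, 18-ROI cohorts at 300 permutations
and 9-sample whole-slide cohorts for the end-to-end patterns, 3000-gene ×
200-unit matrices for the enrichment properties. Floating-point
comparisons: exhaustive nulls match enumeration to 1e-12; analytic KDE
probes to 1e-12; ratio fields are clipped to [0, 1] against accumulation
error; equal-count bin occupancy spread ≤ 1 is asserted exactly.

## Known limitations

- No edge correction in either the NN statistic or the KDE; both inherit
  boundary bias on small fields (shared by observed and null in the
  permutation test, so z is less affected than the raw distances).
- The whole-field permutation null conditions on all cell positions; it
  does not test against CSR, only against exchangeable labels.
- Registration is rigid and grid-limited; no elastic deformation.
- The enrichment score's location bias under widespread effects (above)
  means absolute score thresholds should be calibrated per dataset, e.g.
  by inspecting the score distribution.
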