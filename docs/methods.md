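# Methods

This note documents the models and procedures implemented in `consplan`,
the assumptions behind them, the defaults and why they were chosen, and
what validation on synthetic landscapes does and does not demonstrate.

## Spatial frame

All stages share a planar equal-area grid (`GridSpec`) in kilometre
coordinates with square cells (default 1 km), so occupied-cell counts
convert to areas by multiplication with the cell area. Working directly on
an equal-area plane replaces the map-projection step a real-data analysis
would need; real rasters are accepted only as pre-projected grids. Raster
exchange uses the plain-text ESRI ASCII grid format; tables are CSV; the
prioritizer also writes the Marxan input dialect (`pu.dat`, `spec.dat`,
`puvspr.dat`, `bound.dat`).

## Synthetic landscapes and virtual species

The generator (`consplan.synth`) emulates the statistical structure the
analysis chain assumes, with known truth for validation:

* **Environmental layers** are Gaussian random fields: white noise smoothed
  with a Gaussian kernel (σ = autocorrelation range / cell size) and
  re-standardized to mean 0, sd 1. Default 10 layers (a
  post-collinearity-screen bioclim-style set); a correlation matrix can be
  supplied (Cholesky mixing) to produce 19 raw-style collinear layers that
  exercise the VIF filter. Kernel smoothing was chosen over spectral or
  covariance-decomposition simulation for simplicity and a directly
  controllable range parameter.
* **Future climates** are replicates of the current stack plus a per-layer
  shift and independent autocorrelated noise — stand-ins for global
  circulation models, whose cell-wise mean is the projection surface. The
  pipeline default (five replicates, shift ≈ 0.75 sd scaled per layer,
  noise sd 0.25) produces a directional but model-uncertain climate signal
  strong enough to contract ranges without extinguishing most species.
* **Virtual species** have logistic suitability
  p = 1/(1+exp(−(β₀+Σβⱼxⱼ))) in 2–5 random layers. The truth threshold is
  the suitability quantile whose exceedance set matches a requested
  prevalence (within one cell, ties aside); a constant suitability field is
  rejected as degenerate. Future truth is the same threshold applied to
  the future stack, intersected with current truth under no-dispersal.
* **Occurrences** are presence-only draws (with replacement) from
  true-range cells, uniform or weighted by exp(bias layer) — the spatial
  structure of real sampling bias is unknown, so the bias layer is left a
  free parameter — with coordinates jittered uniformly within the cell.
* **Protected areas** grow as 4-connected random-accretion patches to a
  target coverage (default 10% in 5 patches). **Costs** are strictly
  positive log-Gaussian fields plus Gaussian bumps (amplitude 5, range
  4 km) at settlements, mimicking a human-footprint surface. **Settlements**
  are uniform random points labelled city / institution / museum.

Every generator is a pure function of its arguments and an integer seed.

What the simulator does *not* emulate: realistic climate physics or
inter-variable structure of real bioclim data, non-climatic drivers (land
use, biotic interactions), spatially aggregated occurrence bias,
imperfect detection, and real PA geometry. Passing validation therefore
demonstrates the correctness and internal consistency of the chain under
its own assumptions — not predictive skill on real data.

## Occurrence cleaning

Fixed order: (1) remove records strictly within 10 km of a city or 100 m of
an institution/museum (removal uses `distance < buffer`, so a record exactly
on the edge is retained; both the boundary semantics and the buffers are
configurable); (2) clip to the study mask; (3) thin to one record per
species per cell, keeping the first in input order; (4) drop species with
fewer than 5 records. Each step returns a report whose removal counts are
conserved against the input count. Whether thinning precedes or follows the
proximity filter is immaterial for counts of distinct cells but the order
above is fixed and recorded.

## Ensemble distribution modelling

* **Covariate screening**: VIFⱼ = 1/(1−R²ⱼ) from regressing layer j on the
  others; iteratively drop the largest until all ≤ 10 (perfect collinearity
  is treated as +∞ and removed first).
* **Pseudo-absences**: uniform without replacement from cells holding no
  presence. The count defaults to the presence count — balanced classes
  keep sensitivity and specificity on the same footing in TSS — and is
  configurable.
* **Algorithms**: logistic GLM (unpenalized), random forest (200 trees),
  gradient boosting, RBF-SVM with calibrated probabilities, and an
  L1-penalized logistic model standing as the maxent-like family (same
  presence/background interface, sparse feature selection). Features are
  standardized inside each pipeline where the estimator needs it.
* **Evaluation**: one stratified 80/20 holdout (not k-fold). AUC is the
  rank (Mann–Whitney) statistic; each fit's sensitivity/specificity/TSS are
  taken at its own Max-TSS threshold on the holdout scores; fits with
  TSS ≥ 0.7 are retained. A single-class split is resampled with a bounded
  retry count.
* **Max-TSS threshold**: candidates are midpoints between consecutive
  unique scores plus the endpoints 0 and 1; presence is predicted at
  `score ≥ threshold`; ties resolve to the smallest candidate.
* **Ensemble**: unweighted mean of retained members (a TSS-weighted mean is
  available but off by default, since the retention bar already filters
  weak fits). The ensemble's binarization threshold is the Max-TSS cut of
  its predictions **on the held-out rows**: tree-ensemble predictions on
  training rows sit near 0/1, and thresholding on the full table inflates
  the cut and systematically shrinks predicted ranges (observed directly in
  truth-recovery experiments, where holdout thresholding raised the share
  of species recovered at TSS ≥ 0.9 from roughly half to over 90%).
* **Projection**: suitability on the cell-wise mean of the future
  replicates, binarized at the same threshold; under no-dispersal the
  future range is intersected with the current range. A species whose
  future range is empty is reported as a projected local extinction; a
  species with no retained fit is flagged unmodelled and excluded
  downstream with a logged warning.

## Diversity metrics and comparisons

Richness is the per-cell species count; change is future − current.
Rarity-weighted richness adds 1/cᵢ for each resident species, so the map
total equals the number of extant species — an identity used as a test
invariant. Map agreement uses the Pearson product-moment correlation over
an optional mask (undefined at zero variance, signalled). Paired
comparisons use the Wilcoxon signed-rank test with the normal
approximation: Z is computed from W⁺ centred and scaled by the exact
sign-flip randomization moments (average ranks make the variance
tie-corrected automatically), keeping its sign directional; a rank-sum
variant is provided for unpaired designs. The inside-vs-outside-PA
range-loss comparison is a paired signed-rank test on per-species
proportional losses (cₙₒw − c_fut)/cₙₒw within each region, excluding
species absent from a region now.

## Gap analysis

Protection percentage = 100·|range ∩ PA|/|range|, undefined for an empty
range (reported as a local extinction instead). The five categories are
upper-inclusive bins partitioning [0, 100]: ≤ 10, ≤ 30, ≤ 50, ≤ 80, > 80 —
read literally from their definitions, so exactly 10% is Unprotected and
exactly 80% is Adequately protected. PA masks are cell-aligned.

## Prioritization

Minimum-set formulation over one planning unit per cell:

obj(S) = Σ_{i∈S} costᵢ + blm·B(S) + spf·Σ_f max(0, T_f − H_f(S))

with B(S) the total length of edges between a selected cell and an
unselected or exterior cell (rook adjacency; locked-in cells are part of S,
so shared PA edges contribute nothing and new reserves are encouraged to
clump onto existing ones), H_f the feature amount held, and shortfalls in
km². Numerical choices:

* **Targets**: 100% of range ≤ 1,000 km²; 30% up to 10,000 km²; 10% above
  (the tier boundary at exactly 1,000 km² takes the stricter 100% tier).
* **Statuses**: locked in ⇔ PA overlap; locked out ⇔ within 5 km of a town
  and not locked in (PA overlap takes precedence). Features whose targets
  are unreachable once locked-out units are excluded are flagged
  infeasible at build time.
* **spf** defaults to 10 × the maximum unit cost per km² of shortfall, so
  penalties dominate costs and feasible instances resolve to zero
  shortfall; the penalty is an absolute-shortfall penalty (fully
  specified, hence oracle-checkable by enumeration).
* **Annealing**: start from locked-in ∪ a random half of available units;
  single-unit flips of available units only (lock constraints hold by
  construction); accept downhill always, uphill with probability
  exp(−Δ/T); T₀ set adaptively so ≈ 80% of uphill probe moves (100 probes)
  would be accepted, geometric cooling to 10⁻⁴·T₀; the best configuration
  visited is returned. Defaults: 10,000 iterations × 100 runs
  (`full_scale` raises the portfolio to 1,000 runs — a 10-million
  iteration budget); the pipeline and tests use smaller, stated sizes.
* **Portfolio**: per-run seeds derive from one master seed; outputs are the
  best (minimum-objective) solution and per-unit selection frequencies
  (locked-in units have frequency 1, locked-out 0).
* **Local Moran's I** on any map (selection frequency by default — the
  cluster-analysis input field is a free choice): row-standardized queen
  weights, conditional permutation (each cell's neighbour values redrawn
  from the other n−1 cells; 999 permutations, α = 0.05 by default),
  quadrant labels HH/LL/HL/LH among significant cells. A constant map is
  signalled and returns all non-significant.
* **CPA overlap**: set algebra on the current and future best solutions,
  with per-class cell counts, areas and grid percentages.
* A BLM sweep utility reports the cost/boundary trade-off across candidate
  boundary-length modifiers (default blm 0.001).

## Pipeline

`run_pipeline` executes simulate → prep → sdm → metrics → gap → prioritize
→ report from a single `RunConfig` (YAML-loadable; defaults: VIF 10,
TSS 0.7, buffers 10 km / 100 m / 5 km, tiers 100/30/10%, blm 0.001).
Per-stage seeds are SHA-256 digests of (master seed, stage name), so any
stage rerun in isolation reproduces its part of a full run; a config hash
is written into the run metadata. Stage failures halt with a stage-named
error, retaining partial outputs. The `consplan` CLI exposes each stage and
`all`.

## Problem sizes used in validation

The test suite validates the annealer against exhaustive enumeration on
50 random instances of ≤ 15 planning units (best of 20 runs × 1,500
iterations vs the 2ⁿ optimum), truth recovery on 20 virtual species over a
60 × 60 grid with 200 occurrences each, and target attainment on a 30 × 30
feasible instance — sizes chosen so the full chain exercises every code
path while remaining desk-scale.

## Known limitations

* The maxent-like member is a penalized logistic model, not a full maxent
  implementation (no feature classes or regularization path).
* The annealer implements the standard minimum-set core only: no zoning,
  exact irreplaceability, or block definitions.
* Pseudo-absence contamination (background cells that are truly suitable)
  biases suitability scales for high-prevalence species; thresholding on
  held-out rows compensates for range size but per-cell suitability values
  remain relative, not absolute probabilities.
* The Wilcoxon normal approximation is inappropriate for very few nonzero
  differences (< ~10); the implementation refuses < 3 and callers should
  prefer exact methods for small n.
* Local Moran permutation draws neighbour sets with replacement (the
  standard vectorized scheme); pseudo-p values are approximate by design.
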