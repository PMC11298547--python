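# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the design was genuinely open. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## The pseudospatial model

The organizing assumption is that the ependymoglial lining of the third
ventricle is a one-dimensional expression continuum: each cell has a latent
coordinate *s* ∈ [0, 1] running from typical ependymal cells (dorsal, *s* = 0)
to β2-tanycytes (ventral, *s* = 1), and each gene's expected expression is a
smooth function of *s*. Populations are intervals on the axis; gradients,
bumps and U-shapes are all smooth curves over it.

### Cell ordering (`pseudospace.order_cells`)

*s* is the rank-normalized first principal component of the top-variance
gene space (default `n_top_genes=1000`; a diffusion-map component is
available via `method="diffusion"`). Rank normalization makes *s* invariant
to any strictly increasing transform of the raw axis score and spreads cells
uniformly on [0, 1] — convenient because downstream spline fits then have
even support. Orientation comes from anchor gene sets: the expression-
weighted mean *s* of start-anchor-high cells must be below that of
end-anchor-high cells, otherwise the axis is flipped (exactly, to 1 − *s*);
if the two means are closer than `orientation_tol` the function refuses to
guess. The axis is computed on all conditions jointly, so condition
comparisons (DPSA) share one coordinate system.

This replaces a graph-based trajectory layout: for an unbranched 1-D
continuum the principal axis is equivalent in what it preserves (the
ordering), reproducible, and has no tuning surface beyond the gene count.

### Profile fitting (`pseudospace.fit_profiles`)

Per gene, least-squares regression on a cubic B-spline basis with `df=6`
functions (two internal knots at quantiles of *s*), evaluated on a `G=100`
point grid over [0, 1]; all genes share one design matrix, so fitting is a
single linear solve. df = 6 resolves five populations without ringing on
typical profiles; the split-region study (below) uses df = 8 because its
planted programs are deliberately steep. Curves with grid sd < 1e-8 are
flagged constant and excluded from the standardized set
z<sub>g</sub> = (f<sub>g</sub> − mean)/sd.

## Marker classification (`markers`)

For populations P (default five, ependymal clusters merged into one), the
candidate subsets are all 2⁵ − 2 = 30 non-empty proper subsets — including
non-contiguous ones such as {Epen, β2}, which is what a U-shaped profile
correlates with. The full set is excluded: a gene high everywhere is
housekeeping, not a marker. For every (gene, subset), Pearson *r* between
the gene's normalized expression and the subset's 0/1 cell indicator, with
the exact two-sided p (beta distribution of *r* under the null); BH
adjustment spans the whole gene × subset family. Candidates need *r* > 0 and
p_adj < 0.01 (`alpha`). The winner maximizes score = *r* · *w̄*.

**Weighting choice.** *w̄* is the equal-weight mean of per-population mean
expression over the subset's populations (`weighting="population"`). The
alternative — a plain mean over the subset's cells — lets large populations
dominate combined subsets; equal weighting keeps a {small, large} subset
from being scored as if it were just the large one. The cell-mean variant
stays available as `weighting="cell"`. Ties break toward the smaller subset
(specific beats shared at equal evidence), then lexicographically.

## Unsupervised segmentation (`patterns`)

Standardized curves are clustered with k-means; k maximizes the mean
silhouette over `k_range` (default 5–40), and clusters with ≤ `min_genes`
(default 50) members are dropped. Genes whose *raw* fitted curve has grid
sd < `min_sd` (default 0.1 normalized-expression units) are excluded first:
their standardized curves are pure noise, and clustering them manufactures
patterns whose "transitions" are artifacts. This filter plays the role an
upstream axis-association test plays in GAM-based pattern discovery.

An on–off switch of a consensus curve at threshold *t* is a zero crossing
whose flanking local extrema (endpoints count) reach −*t* and +*t*. Per
threshold (defaults ±0.1 … ±0.5) the pattern × grid switch matrices are
summed into transition scores; summing over thresholds weights a switch by
how many gates its amplitude clears. `call_split_regions` smooths the
aggregate with a centered moving average (`window`, default 5 grid points),
keeps local maxima ≥ `min_frac` (default 0.5) of the global max, merges
maxima closer than the window, and refines each peak to the raw-score
centroid within ± window — smoothing spreads a sharp switch, the centroid
pins it back. Switches are recorded on the right edge of the crossing
interval, so axis reversal mirrors positions up to one grid step.

**Per-pattern vs per-gene.** Transitions are computed on pattern consensus
curves (the spec of the workflow is ambiguous here); `switch_points` works
on any curve, so a per-gene analysis is a one-liner if wanted.

## DPSA (`patterns.compare_conditions`)

Profiles are fitted per condition on the shared grid and integrated axis.
Per gene: Pearson *r* between fed and condition curves with its correlation
p (BH across genes), and the center of mass c = Σ grid·max(f, 0) / Σ max(f, 0)
per condition. A gene is *changed* when the correlation fails significance
at `alpha` or *r* < `r_min` (default 0.8); direction is dorso→ventral when
changed and Δc > δ (default 0.05), ventro→dorsal when Δc < −δ, else none.
The δ dead-band is what keeps noise-only genes (whose condition curves
decorrelate but whose mass stays centered) from receiving direction calls:
on the planted design ~90% of flat genes are flagged changed but under 5%
get a direction. A circular-shift permutation alternative to the analytic
correlation p is available (`tests` exercise the analytic route).

## Pseudobulk DE (`de`)

Within each (population, condition) stratum, cells are shuffled (seeded) and
split into `n_reps=4` groups differing in size by at most one; counts are
summed per group. This conserves counts exactly and manufactures a replicate
axis for count-based testing.

The NB Wald test follows the DESeq2 contract, not its numerics:

1. **Size factors** by median-of-ratios (library-size ratios as fallback
   when no gene is expressed everywhere).
2. **Dispersions**: per-gene method-of-moments estimates using the variance
   pooled *within* design groups (so real fold changes do not inflate
   dispersion), a parametric trend a₀ + a₁/μ fitted to all finite estimates
   — including negative ones; restricting to positive estimates biases the
   trend upward severely at four replicates — and log-space shrinkage of
   gene estimates toward the trend (weight 0.5, floor 1e-8, cap 10).
3. **Wald test** on the condition coefficient of per-gene log-link NB GLMs,
   fitted by IRLS vectorized across genes with the size factors as offsets.
   The statistic is referred to the normal distribution: the trend borrows
   strength across ~2000 genes, so the per-gene variance behaves as known.
   A t reference with (samples − 2) df is available (`use_t=True`) and is
   conservative at this design size.

Calibration is the acceptance surface: on 20 simulated null experiments
(2000 genes, 4 + 4 replicates, dispersion 0.01 — pseudo-replicates are
random splits of one pool, hence near-multinomial, just above Poisson) the
empirical p < 0.05 rate is 0.050, and planted 2-fold genes with base mean
≥ 50 are recovered with sensitivity 0.996 at FDR 0.05. An independent
cross-check against DESeq2 (run via Rscript on one simulated table) verifies
fold-change agreement and significance concordance in the test suite.

**Trajectory classes.** Let s₁₂, s₂₄, s₂₄ᵥ₁₂ ∈ {−1, 0, +1} be the signed
significance states of the 12h-vs-fed, 24h-vs-fed and 24h-vs-12h contrasts
(FDR < `alpha`). Family: I if s₂₄ = +1, D if s₂₄ = −1, T if s₂₄ = 0 but some
step is significant; genes null everywhere are unlabeled. Sub-index, from
(s₁₂, s₂₄ᵥ₁₂): 1 = both steps in the family direction, 4 = early step only,
2 = late step only, 3 = neither step individually, 5 = significant decrease
at 12 h, 6 = significant increase at 12 h with reversal. This encodes the
intended combination semantics — I1+I4 a continuous increase, I1–I4 a global
increase, I6/T6/D6 an increase specific to 12 h, I5/T5/D5 a decrease at
12 h — and yields ≤ 18 labels. Combinations a family cannot produce are
mapped to the nearest shape and flagged (`warn`).

## Communication scores (`ccc`)

For pair (L, R) with sender S and receiver T:
score = mean<sub>S</sub>(L) × R̄<sub>T</sub>, where R̄ is the geometric mean
over receptor subunits of their mean expression in T (AND semantics: a
missing subunit annihilates the score). For single-subunit receptors this
equals the mean over all |S| × |T| cell pairs of the expression product —
the factorization identity the tests verify to 1e-12 against brute force.
Scores are computed per pseudo-replicate (reusing the DE partition, which
gives the ANOVA a replicate axis without inventing a second partition);
one-way ANOVA across conditions per (pair, sender, receiver), BH across
pairs, DeltaScore = mean(condition) − mean(fed). Category summaries report
the percent of significant pairs up/down per sender and signaling class.
A 30-pair toy database in CellChat export format (ligand, receptor with
"_"/"&" subunit separators, annotation, pathway) ships with the package.

## The synthetic generator (`simulate`)

Cells: three conditions × `n_cells_per_condition` (default 1500); population
drawn i.i.d. from the configured fractions; *s* uniform within the
population's interval. Default populations Epen/α1/α2/β1/β2 occupy
[0, .30 / .45 / .65 / .80 / 1] with fractions equal to their widths, so *s*
is uniform overall. Genes: program curves evaluated at each cell's *s* —
specific = raised cosine on the population interval; gradient = logistic
ramp (configurable center and steepness); U-shape = bumps on both end
populations; shifted = an asymmetric bump translated per condition (defaults
+0.1/+0.2 at 12 h/24 h for dorso→ventral sets, mirrored for ventro→dorsal),
clipped at the axis ends without wrap; flat = constant. Planted LR genes use
a flat-top plateau over the sender/receiver interval: replicate-level score
summaries should reflect the planted amplitude change, not within-population
profile variance, which a peaked bump would dominate. Per-condition LR
amplitudes default to ×0.5 (secreted, down), ×2.0 (ECM, up) and ×1.8
(contact, ventral sender) at 24 h.

Intensities get a baseline of 0.1, are normalized per cell to probabilities,
scaled by a log-normal depth (σ = 0.3 around `mean_depth=5000`), and counts
are gamma-Poisson with `nb_dispersion=0.3` (→ Poisson as the dispersion
approaches 0). A small fraction of "damaged" cells (2%) with boosted
mitochondrial load or collapsed depth gives the QC stage something real to
remove. All randomness flows from one `numpy` Generator seeded by
`SimConfig.seed`; identical configs are bit-identical.

`boundary_config()` is the split-region study design: three populations with
boundaries at 0.33/0.66 and steep (rate 0.04) boundary-centered logistic
programs, so every pattern's on–off transition happens at a boundary. This
study uses df = 8 fits and a merge window of 10 grid points: the standardized
zero crossing of a one-sided program sits slightly inside its "on" domain
(by roughly rate × logit of the on-fraction), so the up- and down-ramp
sub-peaks flank the true boundary and the wider window merges them onto it.

**What the generator does not emulate**: ambient RNA, doublets, batch
effects, branching geometry, a second anatomical axis, per-gene outlier
cells, and transcriptome-wide mean–variance structure beyond a single NB
dispersion. Passing tests therefore certify the statistical machinery on an
idealized continuum, not robustness to the full failure modes of real
droplet data — integration and doublet handling are explicitly out of scope.

## QC and normalization

Mitochondrial filter: cells with mito fraction above median + `mad_k` × MAD
(scaled by 1.4826), upper tail only, iterated to a fixed point (recompute on
survivors until stable) — the iteration makes the filter idempotent, at the
cost of removing ~0.3% more cells than a single pass on synthetic data.
With MAD = 0 the cut is the median itself: unequal values above it are still
removed, identical values never are. Min-genes filter: fewer than 200
detected genes. Normalization is total-count scaling to 1e4 + log1p — a
variance-stabilizing regression is not reimplemented; downstream stages
consume normalized expression generically.

## Degenerate inputs and numeric conventions

Flat datasets or failed anchor disambiguation raise typed errors rather than
returning arbitrary orientations; subsets with < 3 cells are skipped in the
marker design; all-zero genes are excluded from DE; pairs with absent genes
are skipped in CCC with a log line; empty pattern sets yield empty profiles
and empty split regions. Ties in k-means are fixed by the seeded
`random_state`; marker ties by subset size then name. BH is used wherever
"adjusted p" appears.

## Problem sizes

The default study scale — 3 × 1500 cells, 2000 genes, 4 pseudo-replicates,
20-experiment DE calibration — keeps the full pipeline and the acceptance
script in the tens of seconds on one CPU while leaving every recovery
statistic with comfortable margin; the unit-test fixtures use 3 × 300 cells
where full scale adds nothing to the property under test.
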