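# Methods

This note documents the models, conventions and design choices behind
`srpkit`, in the order the pipeline runs them, together with the known
limitations of each.

## Range metrics

**MLE.** Range size is the maximum linear extent: the largest pairwise
Euclidean distance among a species' occurrence points, computed on
projected planar km coordinates. Planar rather than geodesic distance is
appropriate for conformal projections at study extents of a few hundred
km; no geodesic hook is provided. All records of a species enter its MLE,
including records flagged outside the study area — a range does not stop
at an administrative boundary — whereas gridded richness uses in-area
records only. Duplicated points never change an MLE; a species with one
distinct point has MLE 0 (a single-site endemic).

**Rarity quartiles.** Species are sorted by MLE with nominal cuts at sort
ranks n/4, n/2 and 3n/4. Real datasets contain large tie blocks (notably
the MLE = 0 block), and a tie block is never split: the whole block joins
the quartile holding the majority of its ranks, with exact half splits
going to the lower quartile. Quartile sizes are therefore unequal whenever
a block straddles a cut — with ~30 % single-site endemics, quartile 1 is
typically inflated and quartile 2 correspondingly shrunk. The majority
rule is one of several tie conventions consistent with published quartile
tables; it is the package's fixed choice. Fewer than four distinct MLE
values leave no quartile structure and raise an error.

**Skewness.** The range-size frequency distribution is summarized by the
plain moment coefficient g1 = m₃/m₂^{3/2} (the small-sample adjusted G1 is
available via `estimator="G1"`). Reported percentages (single-site share,
per-quartile share) are rounded to integer percent, matching how such
tables are printed.

## Grid and richness classes

Cells are half-open squares anchored at a lower-left origin: point (x, y)
falls in cell (⌊(x − x₀)/s⌋, ⌊(y − y₀)/s⌋), so a point exactly on a shared
edge belongs to the higher-index cell. Default cell size is 20 km. Only
occupied cells are kept; a species occupying one cell through several
localities counts once.

Classes relative to the richest cell r_max: class 1 strictly above
85 % of r_max; classes 2–4 include their lower bounds (≥ 60 %, ≥ 40 %,
≥ 20 %); class 5 below 20 %. The asymmetric boundary semantics (strict
only at 85 %) is the unique reading that reproduces the worked-example
minima — hotspot minima of 12 and 19 species for r_max = 14 and 22, SRC
minima of 9 and 14. Because integer richness is compared against
fractional thresholds, comparisons carry a 1e-9 guard against binary
representation error (0.6 × 20 is not exactly 12 in floating point).

Cross-taxon comparison correlates two richness vectors with Kendall's
τ_b. The default cell set is the union of both taxa's occupied cells with
zero fill, because overall patterns are defined over different occupied
sets; an intersection policy is available. The p-value is the asymptotic
normal approximation.

## Stepwise reconstruction

**τ_b.** Implemented from the pair-classification definition,
τ_b = (C − D)/√((n₀ − n₁)(n₀ − n₂)) with n₁, n₂ the tied-pair counts in
either vector. A comparison in which all x or all y are tied is undefined
and returned as NaN — never silently 0 — and NaN steps propagate into
medians via NaN-aware summaries.

**Cells entering τ_b.** By default every occupied cell of the taxon is
used at every step, with subset richness 0 where the subset is absent;
empty cells are informative about mismatch, and the full-support choice
keeps all steps on a common cell set. A `cells="subset"` option restricts
each step to cells the subset already occupies (early steps are then often
undefined); the default is the documented behavior.

**Tie randomization.** Ordering is deterministic for distinct MLEs; every
tie block is shuffled per replicate (the single-site block is merely the
largest such block; `tie_policy="single_site_only"` restricts shuffling to
it). Median curves take per-step medians of τ_b and of %CI over R
replicates (default 10,000; tests and desk runs use 50–500, stated below).

**Null model and empirical p.** The null randomizes the complete addition
order, ignoring MLE. Per step, the 2.5th/97.5th percentiles form the 95 %
envelope, and the two-sided empirical p measures distance from the null
median with the +1/(R+1) correction, so p ∈ (0, 1] and a replicate-equal
observation reports p = 1. Calibration on neutral synthetic data: fresh
random curves sit inside the envelope at ≈ 93–96 % of steps and their
p-values are near-uniform (KS distance ≈ 0.02–0.04).

**Cumulative information content.** CI_k = Σ_{i≤k} pᵢ(1 − pᵢ) with pᵢ the
proportion of the taxon's occupied analysis cells (grid cells, not
localities) occupied by species i. The denominator is fixed at the taxon's
full cell set, which makes total CI order-independent and CI additive over
disjoint species sets. A ubiquitous species (p = 1) contributes nothing; a
half-prevalent species the maximum 0.25.

**Crossing points.** The reported crossing is the smallest k whose τ_b
strictly exceeds the threshold (default 0.5), expressed on both the
%species and %CI axes; a curve that never exceeds returns none.

## Richness GLMs and spatial filtering

**Families.** Log-link Poisson (IRLS via statsmodels) and negative
binomial (NB2). NB dispersion is estimated by alternating IRLS for the
coefficients with a profile-likelihood update of α = 1/θ (Brent search on
log α, bounded in [1e-8, 1e6]), to relative tolerance 1e-8 within 100
rounds; non-convergence raises with the iteration trace. On equidispersed
data α runs to its lower bound and θ is reported as very large — the NB
nests the Poisson. By convention θ counts as an estimated parameter in
AICc's k.

**Fit summaries.** Pseudo R² is explained deviance,
(D_null − D_resid)/D_null: exactly 0 for an intercept-only model, 1 for a
saturated fit, undefined (NaN) for a constant response. AICc adds the
small-sample term 2k(k+1)/(n − k − 1) and is undefined for n ≤ k + 1
(reported NaN on a fit; the standalone function raises). Model residuals
are response residuals y − μ; this is the vector the spatial diagnostics
consume.

**Moran's I correlogram.** All cell pairs are sorted by distance and split
into n_classes (default 14) near-equal-count chunks, so every pair belongs
to exactly one class and class counts differ by at most one (pairs tied on
distance may split across a chunk boundary). Within class c with binary
symmetric weights, I_c = (n/S₀) Σ w_ij z_i z_j / Σ z_i². Significance is a
two-sided permutation test around E[I] = −1/(n − 1) with the +1/(R+1)
correction (default 10,000 permutations, computed in memory-bounded
chunks). Constant values leave I undefined and are flagged as NaN.

**Spatial eigenvector filters.** The classic PCNM construction: pairwise
distances above the truncation t (default 59 km — two rings of neighboring
20 km cells around a focal cell) are replaced by 4t, the matrix −d²/2 is
Gower double-centered, and the positive-eigenvalue eigenvectors, ordered
by descending eigenvalue, are the candidate filters. Eigenvector signs are
fixed (largest-magnitude loading positive) so runs are reproducible;
filters are orthonormal by construction.

**Filter selection.** Forward selection with three rules: (i) candidates
are restricted to filters whose Pearson correlation with the response is
significant at α (no multiple-testing correction at this screening step);
(ii) each step adds the candidate that most reduces the residual
correlogram's worst deviation max_c |I_c − E[I]| of the refit model;
(iii) selection stops when the residual correlogram is globally
non-significant. Global significance uses the Bonferroni-corrected
per-class level α/n_classes — the standard correlogram-wide test — because
with 14 classes tested at raw α the procedure would "find" autocorrelation
in half of all spatially unstructured datasets and select spurious
filters. The permutation count must resolve that level (R ≥ n_classes/α −
1; the function checks). Exhausting all candidates without a clean
correlogram is a warning status, not a failure. On planted-signal
simulations the true filter is recovered, explained deviance rises, and
the focal coefficient moves by well under one nonspatial standard error —
the expected behavior when filters absorb residual structure rather than
confound the predictor.

## Synthetic assemblages

The generator emulates the statistical structure of subterranean
occurrence datasets: each species is single-site with probability
`prop_single_site` (default 0.23; empirical values run ~20–35 %), and
non-single-site MLEs are lognormal (defaults: log-mean 3.2, log-sd 1.2,
i.e. median ≈ 25 km with a long right tail), giving the strongly
right-skewed range-size distribution of real data. The default region is a
650 × 150 km belt gridded into 20 km cells. Locality count grows with
range size (1 + Poisson(rate·MLE/100), floor 2, default rate 8 per 100 km
of MLE), as in real datasets where wide-ranging species accumulate more
records.

Each non-single-site species receives two anchor localities exactly its
drawn MLE apart; remaining localities are placed inside the disc of
diameter MLE spanned by the anchors (radially Gaussian, sd = MLE/4,
rejection-truncated), so the realized MLE equals the drawn MLE to
numerical precision — which makes range-metric outputs exactly predictable
in tests. Ranges may extend past the region rectangle; such records are
flagged out-of-area and count toward MLE but not toward richness.
Positional accuracy is uniform on [0, 10] km so the 6 km accuracy filter
removes a realistic fraction of records.

Scenarios differ only in where range centers fall:

- `common_driven`: top-quartile-MLE species draw their centers around a
  few hotspot centers (Gaussian, sd = `cluster_sd_km`, default 10 km), so
  overlapping common ranges build richness peaks; everything else uniform.
- `rare_driven`: single-site species and the below-median half of ranges
  cluster around the hotspot centers; large ranges are uniform. The
  clustered set is deliberately broader than quartile 1 alone: aggregating
  only the bottom quartile concentrates rare richness into so few cells
  that the many cell pairs elsewhere remain ranked by the diffuse common
  species, and the scenario fails to produce the rare-driven regime it is
  defined to represent.
- `neutral`: all centers uniform.

Under `common_driven`, the descending median curve dominates the ascending
one at ≈ 99 % of steps and escapes the null envelope over a long
contiguous range; under `rare_driven` the dominance drops (typically to
~85–95 % of steps, seed-dependent) — the generator is the lever for this
parameter-recovery check.

What the generator does **not** emulate: karst geology or any habitat
mask, sampling-effort bias (all species are detected wherever they have a
locality), phylogenetic or abundance structure, and any particular spatial
point process of real localities — the clustered-disc model is an
assumption, not an inference from real data. Passing tests therefore show
that the analysis recovers regimes *of this generative form*, not that
real assemblages are identified correctly.

## Determinism, problem sizes, degenerate inputs

Every randomized stage takes an explicit `numpy` Generator or seed; the
pipeline derives independent streams from a single config seed, and
identical (input, config) reruns are byte-identical. Test and acceptance
runs use desk-scale replicate counts — 50–100 tie randomizations per
median curve, 200–500 null replicates, 199–999 permutations — chosen so
the full suite completes in a few minutes; the defaults in
`PipelineConfig` remain 10,000 throughout. Assemblage sizes in tests
(100–150 species, ~150–190 occupied cells) keep every Monte-Carlo check
well-conditioned.

Degenerate inputs are flagged rather than silently absorbed: all-tied
vectors give NaN τ_b; constant responses give NaN pseudo R²; constant
fields give NaN Moran's I; coincident coordinates, empty surfaces, empty
SRC sets, sub-quartile species counts and unresolvable permutation levels
raise errors.

## Known limitations

- The quartile tie rule is a convention; published quartile tables
  constrain but do not uniquely determine it.
- The explained-deviance pseudo R² and the inclusion of θ in AICc's k are
  recorded conventions; other definitions exist and would shift absolute
  (not relative) values.
- Whether stepwise τ_b should use all occupied cells or subset-occupied
  cells is a genuine fork; both are implemented, the all-cells default is
  documented above.
- The Moran permutation test shuffles values uniformly across cells; no
  restricted or toroidal permutation schemes are provided.
- No closed-form null for τ_b under species addition exists here; only
  the Monte-Carlo null. No CAR/SAR/GWR alternatives to eigenvector
  filtering are provided.
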