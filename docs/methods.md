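# Methods

## Model

Samples are modeled as convex mixtures of K archetype expression profiles:
for sample i, xᵢ = Σₖ wᵢₖ aₖ + εᵢ with wᵢₖ ≥ 0, Σₖ wᵢₖ = 1.  Under this
model the population fills a (K−1)-simplex in expression space whose
vertices are the archetypes; Pareto task inference estimates the vertices
and asks whether the simplex is a better description of the data cloud than
chance.  All analysis runs on raw TPM values — deliberately no log
transform, scaling or other preprocessing — after a single informative-gene
filter (sample standard deviation ≥ 1 TPM *and* variance ≥ 1 TPM, n−1
denominators; the two conditions coincide at these thresholds but both are
evaluated as stated).

## PCA and its permutation validation

Two PCA variants are used on purpose:

* **Covariance PCA** (column-centered, unscaled SVD) supplies the
  coordinates for simplex fitting, with a deterministic sign convention
  (largest-magnitude loading entry positive).  Eight dimensions is the
  default, kept from common practice for this analysis.
* **Correlation-matrix eigenvalues** feed the sphericity statistics of the
  permutation validation: Ψ = Σ(λ−1)² and ϕ = √(Ψ/(p(p−1))).  Both vanish
  for uncorrelated standardized data; large values indicate structure that
  justifies dimensionality reduction.

The permutation null shuffles every gene column independently across
samples, destroying inter-gene correlation while preserving marginals.
P-values use the (b+1)/(B+1) correction and therefore can never be exactly
zero: with 100 permutations the smallest attainable value is 1/101 ≈ 0.0099,
which is how a run on strongly structured data reports.  The uncorrected
exceedance fraction is reported alongside for comparison with conventions
that quote "p < 1/B".  A PC counts as significant when its observed
eigenvalue exceeds the 95th percentile of the null distribution of the
same-rank eigenvalue; only the leading run of significant PCs is counted.
Per-PC gene counts are bootstrap-based: samples are resampled with
replacement, projected onto the *reference* loading directions (refitting
PCA per replicate would let component sign and order jitter and artificially
widen the intervals), and a gene counts as significant when the 95%
percentile interval of its correlation with the PC scores excludes zero.
Genes with zero variance in a replicate get correlation 0.

## Simplex fitting

The fitter enforces a strict data constraint: vertices are data points.
For K vertices the volume objective lives in the leading K−1 PCs (the
minimal embedding of a (K−1)-simplex); mixture weights and ESV use all
supplied dimensions, so the 8-PC default applies to the elbow curve while
the volume criterion stays full-dimensional.  The algorithm (recorded in
outputs as `greedy-volume-swap`) is:

1. greedy successive volume maximization — start from a vertex (restart 0
   uses the point farthest from the centroid, further restarts random) and
   repeatedly add the point farthest from the affine span of the current
   set;
2. single-vertex swap hill-climbing to a local optimum, ties resolved to
   the lowest index;
3. best of `n_restarts` (default 10) restarts, ties resolved to the
   lexicographically smallest vertex-index set.

Rows are put in a canonical lexicographic order before seeding, so the
selected vertex *set* is invariant to input row order at a fixed seed.  On
small instances (n ≤ 12) the result matches exhaustive search over all
vertex subsets; this equivalence is exercised in the test suite.  When K
exceeds the embedding dimension plus one (possible during an elbow scan on
low-dimensional data) volume saturates, and additional vertices are chosen
by coverage: the data point with the largest simplex-constrained residual
joins the vertex set.

Weights solve min ‖x − wᵀA‖ subject to w ≥ 0, Σw = 1 via non-negative least
squares on a system augmented with a heavily weighted sum-to-one row.
ESV = 1 − Σ‖xᵢ − wᵢᵀA‖²/Σ‖xᵢ − x̄‖² can be negative for badly underfitted K
in high-dimensional data (a two-vertex segment can explain less variance
than the mean); it is reported unclamped.  K is selected at the elbow of
the ESV-vs-K curve (see below); a decrease of ESV along K larger than 0.05
is treated as a fit failure, smaller fluctuations as restart noise.

## The t-ratio test

t = volume(fitted simplex)/volume(convex hull of the data) in the leading
K−1 PCs; because vertices are data points, t ∈ (0, 1], and values near 1
mean the data essentially fill a simplex.  Significance comes from
refitting under column randomization, with two schemes: shuffle raw gene
columns and recompute PCA per replicate (faithful to the data-generating
claim, slow), or shuffle the PC coordinate columns directly (fast; the
default for large randomization counts).  Both destroy the inter-gene
correlation structure that produces simplex geometry while preserving
marginals.  The test is one-sided (large t significant) with the plus-one
correction; a 10⁵-randomization run on strongly structured data reports the
bound p = 1/(10⁵+1) together with the uncorrected exceedance fraction 0.
Degenerate randomization replicates (rank-deficient hulls) are redrawn and
counted.  Type-I error is calibrated: on i.i.d. Gaussian data the rejection
rate at α = 0.05 sits within binomial error of 0.05 (checked over 200
simulated datasets in the test suite).

Archetype-position uncertainty comes from resampling samples with
replacement, refitting, aligning each replicate's vertices to the reference
fit by minimal-distance assignment (Hungarian), and reporting per-archetype
95% covariance-ellipse areas (π · χ²₂,₀.₉₅ · √det Σ̂) in the PC1–PC2,
PC1–PC3 and PC2–PC3 planes; 1000 replicates by default.

## Archetype-defining genes and the elbow rule

Archetype coordinates are back-projected to gene space as **centered**
reconstructions (loadings · coordinates), so a coefficient is the gene's
deviation at the archetype from the cohort average; adding the PCA means
recovers the reconstructed expression.  Ordered coefficient curves are
cliff-shaped, and the cutoff is the 45°-line elbow: both axes normalized to
[0, 1], the elbow is where a slope −1 line touches the curve.  On the
concave side of the first-last chord this is the point of maximum
perpendicular distance above the chord; on the convex (cliff) side the
tangent point on a discrete noisy curve can slide a few points into the
bulk, so the knee snaps to the dominant value gap near the tangent point —
the discrete analogue of the corner of the idealized right angle.  The two
branches coincide for curves with one sharp bend.  A near-straight curve
(normalized chord distance < 0.02 for the branch decision, < 1e-9 for the
degenerate case) triggers a low-curvature warning and returns the earliest
index.  The rule runs separately on the positive tail and on the magnitudes
of the negative tail; tails with fewer than three genes are kept whole.

Sharing: a gene is shared when it appears (either sign) in ≥ 2 archetype
lists; the summary reports the unique-gene count, the shared fraction, a
symmetric pairwise count matrix and a ribbon table (archetype pair, gene,
sign in each) for circular-plot tools.

## Enrichment and attribute association

Gene-set enrichment is the one-sided hypergeometric tail
P(X ≥ overlap) with universe = genes surviving the informative-gene filter
(the sampling frame of candidate defining genes, not the genome), sets
intersected with the universe first, BH-FDR across sets per list.
Archetype–attribute association bins the ⌈0.1·n⌉ samples with the highest
mixture weight on the archetype (ties by sample id; `bin_fraction`
configurable and recorded): discrete attributes get a per-category
hypergeometric over-representation test of the bin against the non-missing
cohort (effect = prevalence ratio), continuous attributes a two-sided
Mann-Whitney bin-vs-rest comparison (effect = median difference, in the
attribute's units).  Mann-Whitney uses an exact tie-aware enumeration null
for combined n ≤ 20 and the tie-corrected normal approximation otherwise.
BH adjustment runs across the archetype × category (resp. archetype ×
attribute) family; missing values are excluded test-wise.

## Synthetic cohorts and what they do (not) show

`generate` draws per-gene baselines from Uniform(2, 6) TPM, mixture weights
from Dirichlet(α = 0.35 symmetric; vertex-concentrated so the simplex is
populated out to its corners), adds i.i.d. Gaussian noise (σ = 2 TPM
default) and truncates at zero — truncation rather than resampling, a mild
departure from purely additive noise that preserves TPM non-negativity.
Planted defining genes sit on an elevated baseline (+signal, so depressed
levels stay non-negative) with deviation `signal` = 20 TPM (10× the default
noise).  The default cohort is 300 samples × 1000 genes with 30
defining-gene slots per archetype.

Deviations from the cohort mean are zero-sum across archetypes in a convex
mixture, which shapes the planted structure:

* **Shared** genes are opposite-sign pairs (+signal at one archetype,
  −signal at another, baseline elsewhere) — trade-off genes with *zero*
  deviation at the uninvolved archetypes.
* **Unique** genes deviate at a single archetype and therefore carry real
  opposite-sign "echo" deviations of magnitude signal/(k−1) at every other
  archetype.  These echoes are genuine biology of the mixture model but are
  not part of the nominal truth lists, so selection on cohorts with many
  unique genes legitimately reports more sharing than the nominal planted
  fraction.  The defining-gene recovery benchmark therefore runs at
  `shared_fraction = 1` (all-pair cohorts), where the ground truth is
  unambiguous; there precision and recall are ≥ 0.9 per archetype and sign.

The discrete label follows P(target category) = 0.2 + 0.7·w (clipped),
strong but not deterministic; the continuous covariate is
2 + 8·w + N(0, 1).  The generator does not emulate count noise
(negative-binomial), batch effects or library-size artifacts, so passing
tests demonstrate correctness of the inference chain under the mixture
model, not robustness to those real-data phenomena.

`recovery_error` matches fitted to true archetypes by Hungarian assignment
on Euclidean distances (gene space; PC-space inputs are back-projected) and
returns the mean matched distance.

## Problem sizes and numerical choices

Test-bench and analysis problem sizes are chosen to make the statistical
claims measurable on a single CPU in minutes: 300 × 1000 cohorts, 100
permutations for PCA validation, 10⁴–10⁵ randomizations for the t-ratio
(the fast PC-shuffling scheme with 4 restarts per refit for the largest
runs), 1000 bootstrap replicates, 200-dataset calibration loops.  Weight
decomposition tolerance comes from NNLS on the augmented system (sum-to-one
weight 10⁴ × the coordinate scale, renormalized exactly afterwards);
simplex-volume ties break toward lower indices; all stochastic stages take
explicit seeds, and the pipeline derives per-stage seeds from a master seed
and the stage name via SHA-256.

## Known limitations

* The maximum-volume fit is a heuristic local optimum; exhaustive
  equivalence is verified only at small n, and distinct restarts can give
  slightly different ESV at large K (handled by the 0.05 monotonicity
  tolerance).
* The elbow rules (K selection and gene cutoffs) are geometric conventions;
  near-straight curves are flagged but still answered.
* With attribute bins defined by weight quantiles, discrete-attribute
  p-values are mildly conservative under the null (the bin size is fixed,
  the hypergeometric is exact); calibration is verified as an upper bound.
* Headline quantities from the motivating cohort-scale analyses (e.g.
  eigenvalue magnitudes on 22k-gene matrices) scale with cohort size and
  are reproduced here structurally on synthetic data, not numerically.
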