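# Methods

This note documents the models, numerical choices and limitations of
the package, and what the synthetic generators do and do not emulate.

## Trait space construction

**Landmarks and GPA.** Each girdle is described by 18 named 3D
landmarks (mm). Right-side configurations are reflected across one
coordinate plane onto the left before superimposition, because the
alignment is rotation-only (orthogonal Procrustes with det = +1;
reflections are never introduced by the optimizer). Generalized
Procrustes analysis translates each configuration to centroid origin,
scales it to unit centroid size, and iteratively rotates all
configurations onto the evolving mean shape; the mean is re-centered,
re-scaled to unit size and rotationally aligned to its predecessor each
round. Convergence: change in mean shape (root-sum-square over
coordinates) < 1e-10, at most 200 iterations. The aligned coordinates
are used directly as shape variables — no tangent-space projection and
no principal-component reduction. The 7 redundant degrees of freedom a
3D superimposition leaves behind are deliberately retained: downstream
z-scoring would distort PC scores, whereas redundant coordinates are
harmless to the vector analyses.

**Centroid size** (√Σ‖xᵢ − x̄‖²) of the pelvic girdle is the body-size
proxy; lengths (15) and thicknesses (8) are divided by it per specimen.
Bone cortical thickness is ingested as the already-averaged
cross-section measurement; the package does not re-derive it from
images.

**Imputation.** Missing linear measurements are completed by iterative
PCA: missing cells start at column means, then alternate rank-q SVD
reconstruction (q = 3 by default, configurable) with replacement of
missing cells only, until the largest change < 1e-8 (max 500
iterations). Observed cells are never altered; an entirely missing row
or column is an error; a missing fraction above 10% warns.

**Standardization.** Every column is z-scored with the sample standard
deviation (n − 1). The scaling population is an explicit argument of
the pipeline ('museum' rows by default; experimental rows are projected
onto the museum scale via the stored per-column mean/sd record). This
matters: trajectory lengths L are in per-trait standard-error units and
change with the scaling population, so the record is carried alongside
the matrix.

**Repeatability.** Replicated digitizations are superimposed together;
a Procrustes one-way ANOVA (sums of squared deviations pooled over all
landmarks and axes, individual as factor) gives MS_among and MS_within;
R = s²_A/(s²_A + MS_within) with s²_A = (MS_among − MS_within)/k₀ and
the standard unbalanced-design correction k₀ = (N − Σkᵢ²/N)/(n − 1),
clamped to [0, 1].

## Trajectory analysis

The trajectory between two groups is the 132-vector of per-trait
two-sample t-values, sign convention mean(A) − mean(B). The Welch
statistic is the default; a pooled-variance switch exists because the
choice is not dictated by the method and both are defensible. A trait
with zero variance in both groups gets t = 0 with a warning rather
than aborting a dataset-wide sweep.

Angles are computed with the dot/norm ratio clipped to [−1, 1] before
the arccos, so Θ is always defined in [0, 180]. ΔL = L(a) − L(b) is
antisymmetric by construction.

**Quartets.** All ecomorph-pair × island-pair combinations where both
ecomorphs have ≥ min_n (default 2) specimens on both islands, in
deterministic lexicographic order. Under the default island design
(below) exactly 53 of the 90 nominal combinations survive.

**Permutation test of parallelism.** Island labels are shuffled among
each ecomorph's specimens across the two islands, preserving per-island
cell sizes — divergence itself is preserved while island identity is
destroyed, which is precisely "simulated parallelism". Both trajectory
vectors are recomputed per permutation; p_parallel is the smoothed
upper-tail probability of the observed Θ under this null, p_length the
analogue for |ΔL|. p-values use (count + 1)/(N + 1) smoothing, so they
are never zero. An alternative scheme that shuffles islands across the
whole quartet's specimens is available behind a flag; the
within-ecomorph reading is the default because the labels being
exchanged are islands of origin for a fixed ecomorph contrast.

**Bootstrap test against orthogonality.** Specimens are resampled with
replacement within each of the four ecomorph×island cells;
p_orthogonal is the smoothed fraction of bootstrap angles ≥ 90°.

**Classification.** "Indistinguishable from 0°" is operationalized as
failure to reject the parallel permutation null (p_parallel ≥ α);
"indistinguishable from 90°" as failure to reject orthogonality; both
rejected places the quartet between. Rejecting neither is logically
possible at low power and is flagged ambiguous with a warning instead
of being forced into a category. α = 0.05 throughout; no
multiple-testing correction across quartets is applied, matching the
analysis design this package implements. Species non-independence
within cells is ignored (specimens pooled).

**Outlier scans.** A trajectory's t-values are z-scored against their
own 132-value distribution; traits beyond the two-sided normal
quantile at prob = 0.95 (|z| > 1.645) are its signature traits. On an
iid standard-normal vector this flags ≈ 13.2 traits on average — the
scan identifies relative outliers, not absolute significance.

**Determinism.** Every stochastic operation takes an explicit seed; the
pipeline derives per-quartet seeds from the master seed by CRC32
hashing of the quartet label (kept below 2³¹), so whole-run reports are
bitwise reproducible while Θ and ΔL remain deterministic given data.

## Convergence

Wheatsheaf index: Euclidean distances between species means of the
scaled traits, divided by the penalty √(tᵢⱼ/t_max) (patristic distance
over matrix maximum) so that close relatives' phenotypic similarity is
discounted; w = mean penalized distance over all pairs / mean over
focal pairs. The penalty preserves the reference method's
ratio-of-means structure and penalty direction but may differ from the
original implementation in constants, so only order and significance —
not raw index values — should be compared across implementations; all
checks of this module are property-based for that reason. Zero
patristic distances between distinct tips borrow the smallest positive
distance to keep the divisor finite. Species means are computed after
standardization with no SE weighting (scaled values carry no meaningful
standard errors). Significance: n_perm (default 999) size-matched
random focal sets, smoothed upper tail. The per-trait scan reuses one
set of permutation draws across traits for speed; draws are seeded.

## Sex assignment

Two-class LDA with pooled within-class covariance, priors proportional
to training frequencies (equal-priors switch available). Because 54
pelvic shape variables can exceed class counts, the covariance is
shrunk toward its diagonal (coefficient 0.1 by default; None disables
it on full-rank data, restoring exact affine invariance). Assignments
are accepted at posterior ≥ 0.8; split validation is stratified 60/40
and reports accuracy among accepted assignments plus the acceptance
rate.

## Synthetic data: what it emulates, and what it does not

The radiation generator reproduces the comparative design's statistical
skeleton: 95 species on a unit-height pure-birth tree; four islands ×
six ecomorphs with three island–ecomorph absences (defaults: Jamaica
lacks trunk; Puerto Rico lacks trunk and crown-giant — the nesting of
absences is what yields exactly 53 quartets, and the trunk ecomorph
genuinely occurs only on two islands; the mapping is configurable);
1 + Poisson(1.73) individuals per species capped at 14 (mean ≈ 2.7,
≈ 260 specimens). Species means = Brownian motion (rate σ² = 1 per
trait) + a shared ecomorph effect vector (per-trait sd 1.5) + δ × an
island-specific deviation (δ = 0.5 by default; δ = 0 makes island
trajectories exactly parallel in expectation); individuals are iid
Gaussian (sd 1) around species means. Missing linear cells are deleted
at rate 0.53%.

Landmark emission deforms a unit-size template inside an orthonormal
basis (coefficients taken from the latent shape traits, scaled into
the small-deformation regime), adds isotropic landmark noise, and
applies a random rotation, translation and per-specimen body scale
(lognormal around 20 mm pelvic centroid size, driven by the latent
size trait); 5% of configurations are emitted right-sided. Raw linear
measurements modulate positive mm baselines by exp(0.04 × latent) and
share the body scale, so size correction genuinely removes it.

The plasticity generator reproduces the rearing experiment's sample
sizes (41/34 and 22/23 males per treatment for the runner and climber
species) and constructs the treatment effect vector at an *exact*
target angle to a supplied divergence vector by Gram–Schmidt mixing,
with trait-space magnitude 30 (units of the individual noise sd) — a
strong-signal regime chosen from the sampling model: the angle
estimate's noise floor is ≈ atan(√p/s) with s = √(n/2)·magnitude, about
6–7° at per-group n = 40 for a 0° target, falling as the target grows.
Recovery of a 0° injected angle therefore sits close to that
structural floor; this is a property of t-vector estimation at finite
n, not of the generator.

Not emulated: within-species phylogenetic structure (individuals are
iid around species means), Ornstein–Uhlenbeck or multi-rate trait
evolution, biomechanical structure in bone responses, measurement
covariance between neighbouring landmarks, and sparse per-trait
convergence — the shared ecomorph effects make *every* trait convergent
for every ecomorph, so per-trait signature scans flag densely on
synthetic data where real data would flag sparsely. Passing tests
therefore demonstrate calibration and recovery of the estimators under
the assumed sampling model, not the biological sparsity patterns of any
real radiation.

## Problem sizes and tolerances

Test-suite and acceptance-script runs use the full 95-species design
for structural checks, with 199 permutations/bootstraps per quartet and
reduced replicate counts for calibration studies (200 datasets for
type-I error, 100 replicates per injected angle, 300 for p-uniformity);
these sizes give Monte-Carlo error comfortably inside the asserted
bands while keeping a full run to a couple of minutes on one CPU.
Numerical tolerances: GPA convergence 1e-10; imputation 1e-8;
standardization invariants 1e-10; closed-form geometry checks 1e-9.

## Known limitations

- The Wheatsheaf penalty constants may differ from the original
  reference implementation (see above); cross-implementation index
  values are not comparable digit-for-digit.
- The bootstrap orthogonality test is optimistic when cells contain a
  single specimen (resampling is degenerate; a warning is emitted).
- Grafting a tip assumes the sister's terminal branch is positive and
  places the attachment at a configurable fraction (default 0.5) —
  divergence times of grafted species are not estimated.
- The pipeline treats specimens as exchangeable within ecomorph×island
  cells; species identity is not a random effect anywhere.
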