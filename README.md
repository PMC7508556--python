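# ecomorph

Comparative morphometrics of repeated island radiations: do pairs of
ecologically specialized forms ("ecomorphs") diverge along the *same*
multivariate direction on different islands?

The package implements the full inference chain used to answer that
question for the locomotor skeleton of Greater Antillean *Anolis*-style
radiations, from raw 3D landmarks and bone measurements to significance
tests of parallel evolution — together with a synthetic-study generator
that reproduces the design's statistical structure with known ground
truth, so every estimator can be validated by parameter recovery.

It is written for evolutionary biologists doing geometric morphometrics
and phenotypic trajectory analysis: the library (`src/ecomorph/`) holds
every computation, the numbered scripts under `analysis/` narrate the
study end to end, and a small CLI (`ecomorph`) wraps the pipeline.

## The method

**Trait space.** Each specimen contributes 132 traits: 54 + 54
Procrustes shape variables (18 3D landmarks per pectoral and pelvic
girdle, right sides mirrored, generalized Procrustes superimposition
with rotation-only alignment and no tangent projection), 15 limb-bone
lengths and 8 long-bone thicknesses divided by pelvic centroid size
(the body-size proxy), and centroid size itself. Missing measurements
are imputed by iterative PCA. Every column is then transformed to
standard normal deviates, z = (x − x̄)/s, so shape and linear traits
live on one commensurate scale.

**Trajectories.** For a pair of ecomorphs on one island, the divergence
trajectory is the vector **a** of per-trait two-sample t-values (Welch
by default). Two islands' trajectories are compared by

  Θ = arccos [ Σaᵢbᵢ / (√Σaᵢ² · √Σbᵢ²) ] · 180/π,  ΔL = √Σaᵢ² − √Σbᵢ²

Θ = 0° means parallel divergence; unrelated random directions average
90°. Significance: island labels are permuted within ecomorph to build
the parallel null for Θ and |ΔL| (p = (count+1)/(N+1)); specimens are
bootstrapped within each ecomorph×island cell to test Θ against 90°.
Each quartet is classified as indistinguishable from 0°, between 0°
and 90°, or indistinguishable from 90°. Outlier scans of a trajectory's
132 t-values (two-sided 95th percentile of its own distribution)
identify its signature traits.

**Convergence.** Per-ecomorph Wheatsheaf index: the ratio of mean
phylogenetically penalized phenotypic distance over all species pairs
to the mean over focal-ecomorph pairs (penalty divisor √(tᵢⱼ/t_max)
from patristic distances tᵢⱼ); w > 1 indicates the focal group is
phenotypically tighter than its phylogeny predicts. Significance by
size-matched random focal sets.

**Sex assignment.** A linear discriminant on pelvic shape variables
(shrinkage-regularized pooled covariance), accepting assignments only
at posterior ≥ 0.8, validated by a stratified 60/40 split.

## Worked example

```python
import ecomorph as em

# a full synthetic radiation: 95 species, 4 islands, 6 ecomorphs
rad = em.simulate_radiation(em.simulate_tree(95, seed=42),
                            em.RadiationParams(seed=42))
tm = em.standardize(rad.traits)
quartets = em.enumerate_quartets(rad.metadata)
print(len(quartets))                      # 53

res = em.analyze_quartet(quartets[0], tm.values, rad.metadata,
                         n_perm=199, n_boot=199, seed=1)
print(round(res.theta, 2), res.classification)
```

prints

```
53
37.65 between_0_and_90
```

53 is the number of usable ecomorph-pair × island-pair comparisons
under this island design (three island–ecomorph absences remove 37 of
the 90 nominal combinations). The first quartet's divergence
trajectories meet at ≈38°: significantly more parallel than random
(90°) but distinguishable from perfectly parallel (0°) — exactly the
"moderate but consistent parallelism" regime the default generator
(island-deviation scale δ = 0.5) produces. Running the numbered
scripts in `analysis/` reproduces the whole study narrative; small
result tables land in `results/`.

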