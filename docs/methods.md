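# Methods

## The measurement

Unhealthy white matter connectivity (UWMC) treats the structural
connectome as a transport network and asks what fraction of each
connection is routed through damaged tissue.  Inputs per subject are
(a) a whole-brain tractogram (polylines in world mm), (b) an integer
parcellation volume with a label table, and (c) a binary WMH mask, all
co-registered to one grid.  A streamline contributes to the unordered
region pair {i, j} only when its first and last points fall in labels i
and j with i ≠ j ("end-to-end"); streamlines with an unlabeled endpoint or
both endpoints in one region are ignored.  Writing T and U for the total
and lesion-crossing tallies of a pair:

- pairwise UWMC = U/T (pairs with T = 0 are reported as 0 and flagged);
- lobar UWMC = ΣU/ΣT over pairs with both regions in one bilateral lobe
  (a ratio of sums — pairs with many streamlines weigh more — not a mean
  of per-pair ratios);
- global UWMC = ΣU/ΣT over every pair in the brain.

All streamlines count equally; there is no length or volume weighting.

### Intersection geometry

A streamline "passes through" the lesion when it crosses at least one
true mask voxel; no minimum overlap length is required.  The default test
is exact: each segment is mapped to continuous voxel-index space (where
the cell of voxel k is the half-open cube [k−½, k+½)), the parameters at
which it crosses half-integer planes are enumerated, and the voxel between
consecutive crossings is read off at the interval midpoint.  This visits
every cell the segment geometrically intersects, so it agrees with a
brute-force segment/box-clipping oracle and cannot miss corner-clipped
voxels the way pointwise sampling does (in pre-tests, half-voxel point
sampling missed the lesion on ~4% of random streamlines).  An approximate
pointwise mode (`IntersectionConfig.sampling_step`, in mm) is retained for
speed comparisons and sensitivity analyses.

Endpoint labels use nearest-voxel lookup at the endpoint coordinate.
With `endpoint_dilation` d > 0, an unlabeled endpoint voxel is assigned
the majority nonzero label within a Chebyshev radius of d voxels (ties →
unlabeled).  The default is d = 0, i.e. exact-voxel matching.

Voxel indices are 0-based; world coordinates are RAS mm; TRK voxel-space
dialects are converted on read using the transform in the file header, so
both TCK and TRK yield identical world-mm polylines.  Coordinates are
standardised on world mm throughout.

## WMH segmentation

FLAIR intensities are z-scored against the voxels of a cerebellar
white-matter reference mask: x → (x − μ_ref)/σ_ref, so the reference has
mean 0 and SD 1 afterwards.  Cerebral voxels (any user-supplied cerebral
mask) are then soft-clustered by plain two-class fuzzy c-means on the 1-D
normalised intensity: minimise Σ_i Σ_k u_ik^m (x_i − c_k)² with
memberships u_ik ∝ |x_i − c_k|^(−2/(m−1)) normalised to sum to 1 per
voxel.  The cluster with the larger converged centroid is "high
intensity", and a voxel is WMH when its high membership strictly exceeds
0.75.

Defaults and their reasons:

| parameter | default | rationale |
|---|---|---|
| fuzzifier m | 2.0 | the classical choice; larger m blurs memberships |
| initialisation | centroids at 10th/90th percentile of in-mask intensity | deterministic, avoids label-swap ambiguity; no RNG needed |
| convergence | max centroid move < 1e-5, ≤ 300 iterations | centroid movement is the natural scale-free stopping rule |
| threshold | 0.75, strict `>` | membership exactly 0.75 is *not* WMH |

The objective is checked to be non-increasing across iterations.  The
clustering is intensity-only with no spatial regularisation, no minimum
cluster size and no manual editing stage.  Two consequences worth knowing:
all in-mask voxels identical is a degenerate input (error), and when the
lesion fraction is far below ~1% the high centroid is captured by the
upper tail of the normal-tissue distribution rather than the lesion mode —
two-class intensity clustering needs an appreciable second mode.  The
segmenter is therefore validated on mixtures with ~5% lesion voxels and a
6 SD separation, where it recovers the planted mask with Dice ≥ 0.9.

## Lesion volumetry

Lobar WMH volume = (number of WMH voxels carrying that lobe's label) ×
voxel volume, with voxel volume = |det A₃ₓ₃| of the affine.  Each lobar
volume is divided by intracranial volume (ICV voxel count × voxel volume)
to give a unitless ratio.  WMH voxels outside the four lobes are tallied
under "other", never dropped.  Published tables in this literature print
normalised WMH on an unstated scaled axis; the package reports the raw
ratio and offers a display multiplier (default 1) rather than guessing a
hidden constant.

## Statistical pipeline

The cohort analysis relates UWMC to global cognition (MoCA, 0–30 points,
higher = better) adjusting for age, sex, racialized group (full-sample
models only), education, physical activity, diabetes, hypertension, high
cholesterol and APOE ε4 carriage.

1. **Transforms.**  UWMC fractions and physical-activity hours are
   natural-log transformed after substituting 0.05 for exact zeros (zeros
   are real data — every pair without lesion-crossing streamlines — and
   must survive the log).  Natural log is what makes the β/100 reporting
   rule valid: β·ln(1.01) ≈ β/100 is the MoCA difference per 1% greater
   UWMC.

2. **Data reduction** (`stability_select`).  With hundreds of candidate
   pairs and ~200 participants, individual regressions need a screening
   stage.  120 times: draw a fresh simple random 90% of participants
   (round(0.9·n), without replacement, seeded `master_seed + rep`),
   standardise the candidate features on that subsample, and fit an
   elastic net of MoCA on the features with the covariates forced in
   unpenalised.  Unpenalised covariates are handled by exact
   partialling-out: minimising ‖y − Zγ − Xβ‖² + pen(β) over an
   unpenalised γ is algebraically identical to the elastic net of the
   Z-residualised outcome on the Z-residualised features (the penalty
   never touches γ).  The penalty is chosen per repetition by 10-fold
   cross-validation on a 40-point path, taking the largest penalty within
   one standard error of the minimum mean-squared error (the 1-SE rule).
   A feature is "chosen" in a repetition iff its coefficient is nonzero;
   features chosen in ≥ 90% of repetitions are selected.

   The mixing parameter defaults to 0.9 (90% lasso / 10% ridge).  Both
   the lasso-leaning mixing and the 1-SE rule exist for the same reason:
   at the CV-minimum penalty with an even l1/l2 mix, weakly correlated
   null features keep tiny nonzero coefficients in nearly every
   repetition, so their selection frequencies do not separate from the
   signal and the 90% threshold loses its meaning.  With the sparser
   defaults, planted-signal cohorts (3 active features of 50, standardized
   effect 0.5, n = 300) are recovered exactly and pure-noise cohorts
   select nothing, across seeds.  Both knobs are configurable.

3. **Robust regressions** (`huber_regression`).  One model per selected
   feature: MoCA on the log feature plus covariates, estimated by IRLS
   with the Huber ψ at tuning constant 1.345 (95% efficiency under
   Gaussian errors), scale re-estimated each iteration by the median
   absolute deviation, convergence on coefficients at 1e-8.  Standard
   errors come from the asymptotic M-estimator formula and p-values from
   the large-sample normal reference.  UWMC data contain gross outliers;
   the bounded ψ keeps a handful of extreme participants from steering
   the slope (verified against least squares under planted 10%
   contamination).  When no residual exceeds 1.345·scale the estimator
   coincides with least squares, which is asserted in the tests.  Models
   are fitted in the full sample and separately in each racialized-group
   stratum (the group covariate is dropped there).

4. **Multiplicity and interaction.**  Within each analysis column (full,
   and each stratum) the uncorrected p-values form one family and are
   controlled by Benjamini–Hochberg step-up at q = 0.05.  A
   group-by-feature interaction is tested in the full sample only when
   exactly one stratum's association survived FDR — when both or neither
   did, there is no group difference to explain and the interaction is
   reported as "–".  Applied to the published full-sample p-value columns
   shipped with the package, this BH implementation reproduces the
   printed rejection counts (17 of 18 amyloid pairs, 5 of 8 tau pairs).

5. **Validation and descriptives.**  Lobar UWMC is validated against
   lobar WMH volume by Spearman rank correlation (average ranks on ties).
   Group descriptives (by racialized group, or by high/low global UWMC
   with values equal to the median assigned to "high") use Mann–Whitney U
   for continuous variables and chi-square for binary ones, switching to
   Fisher's exact test when any expected cell count is below 5.

`CognitionAnalysis` wraps stages 1–4 as a model object whose `fit()`
returns an `AnalysisResults`; `summary()` renders the association table
(β to 2 decimals, per-percent effects to 3, p-values floored at
"< 0.0001").

## Synthetic data

`make_phantom` builds spherical labeled ROIs, draws each bundle's
streamlines as gently bowed polylines with endpoints strictly inside the
spheres (so endpoint labeling is unambiguous at zero dilation), and plants
the lesion from the voxels traversed by the designated unhealthy
streamlines' middle sections, minus every voxel touched by any healthy
streamline (at 0.01 mm sampling) and every ROI voxel.  The plant is
verified streamline-by-streamline with both the dense-sampling oracle and
the pipeline's exact traversal, and retried with fresh curvature when
infeasible — so the planted per-pair UWMC equals the pipeline-computed
value exactly, which is the package's core end-to-end check.  FLAIR is
synthesised as N(0, 1) background with lesion voxels shifted by +6 and a
disjoint corner box as the cerebellar reference.  `target_uwmc ×
n_streamlines` must be an integer; fractions are planted exactly, not in
expectation.

`make_cohort` draws covariates from documented distributions (age uniform
50–89; sex ~ Bernoulli(0.667); group ~ Bernoulli(0.5); education ~
N(14, 2.5²) clipped to 8–20; physical activity log-normal with median
~9.3 h/week; vascular-risk and APOE prevalences 0.17/0.38/0.35/0.31) and
per-pair UWMC fractions from a Beta(1.2, 6) — right-skewed with mass near
zero, resembling observed lobar medians of roughly 0.06–0.18 — with an
optional location shift of the Beta mean for one group (default +0.04),
reproducing the qualitative group difference in lesion burden.  MoCA is
intercept (26) + Σ β·ln(UWMC, 0→0.05) + covariate effects + N(0, σ²),
clipped to [0, 30] and rounded; clipping/rounding can be disabled for
exactness checks.  Active effects can be specified per SD of the realised
log-feature (`standardize_active`), which is how the recovery suites pin
the signal-to-noise ratio.

What the generators deliberately do not emulate: MRI physics (bias
fields, partial volume, motion), anatomically realistic fibre geometry or
lesion shapes, correlated UWMC features (each pair is drawn
independently), and the real cohort's exact distributions.  Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the stated generative model, not clinical validity on real scans.

## Problem sizes and numerical choices

The test and acceptance suites run on phantoms of ≤ 64×48×24 voxels with
4–24 streamlines, 1000 random streamlines for geometry oracles, and
cohorts of n = 300 with 50 features; stability-selection recovery is
evaluated over 20 independent seeds of 120 repetitions each.  These sizes
were chosen as the smallest at which each claim is sharply testable.
Ties in the endpoint-dilation majority vote return "unlabeled" rather
than guessing; voxel-boundary coincidences in the exact traversal follow
numpy's rint convention and are measure-zero for continuous inputs;
pathology-set extraction returns all n(n−1)/2 candidate pairs of a
flagged region set, leaving any study-specific exclusions to
configuration.

## Known limitations

- The default label table reconstructs plausible amyloid (42-region) and
  meta-temporal tau (12-region) sets over Desikan–Killiany + striatal
  names; studies should supply their own table when exact set membership
  matters.
- Two-class intensity-only FCM is unreliable when lesions occupy far less
  than ~1% of the cerebral mask (see above); supply a precomputed mask in
  that regime.
- Streamline counts are unweighted; siblings of UWMC based on
  length-weighted or volume-weighted tallies are out of scope.
- Tractography quality control (alignment checks, pruning) is assumed to
  have happened upstream; the pipeline logs streamline counts but does
  not prune.
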