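# Methods

## Problem and model

Screen-detected indeterminate pulmonary nodules are surrounded by
macro-vasculature — arteries and veins outside the nodule itself — whose
architecture carries information about malignancy (tumour angiogenesis
recruits vessels in the peri-nodular region). The package quantifies this
architecture from 3-D segmentation masks and models malignancy from the
resulting feature table.

For each nodule, arteries and veins are quantified in **cumulative distance
bands** of 5, 10, and 15 mm measured from the nodule surface, excluding all
vasculature inside the nodule. Per compartment and band three metrics are
computed:

- **branch count** — the number of skeleton branches intersecting the band;
- **volume** — vessel-mask voxels in the band × voxel volume, in cm³;
- **tortuosity** — mean over branches of curved length / chord length of
  the in-band skeleton sub-path (≥ 1 by construction).

Bands are cumulative (distance ≤ d, boundary inclusive) rather than disjoint
shells, which makes counts and volumes non-decreasing in d within every
subject — an invariant the test-suite checks on every extraction.

## Band feature extraction

1. **Distance map.** Exact Euclidean distance transform of the complement of
   the nodule mask with anisotropic spacing (`scipy.ndimage`). Values are
   signed: positive outside, zero on surface voxels, negative inside;
   interior voxels are flagged and can never enter a band.
2. **Skeletonization.** The vessel mask restricted to the nodule exterior is
   thinned to a one-voxel 3-D skeleton (`skimage.morphology.skeletonize`),
   then decomposed into branches: maximal 26-connected paths between nodes
   of degree ≠ 2 (junctions or tips); an isolated cycle is one closed
   branch. The skeleton is built **once** per compartment; a branch belongs
   to a band if any of its skeleton voxels lies in the band, and its
   tortuosity is measured on the in-band sub-path (the longest contiguous
   run if a branch crosses the band boundary more than once). This keeps
   counts consistent across nested bands.
3. **Curved length.** Summing consecutive voxel-centre distances along a
   digital path inflates the length of oblique straight lines by up to ~8%,
   which would swamp a tortuosity signal of a few percent. Curved length is
   therefore measured on a lightly smoothed polyline: a moving average over
   a 2 mm window applied to interior vertices with the endpoints pinned.
   Because the endpoints are fixed, smoothed length ≥ chord always holds.
   On digitized oracles (0.5 mm spacing) this estimator reproduces
   tortuosity 1.0 for straight tubes within 0.01 and π/2 for a semicircular
   arc within 0.01.
4. **Short paths.** A sub-path shorter than 2 mm (≈ a few voxels) carries no
   tortuosity information — its curved/chord ratio is dominated by
   digitization noise. Such branches still count and contribute volume but
   are excluded from the band's tortuosity mean; the phantom ground truth
   applies the identical rule. An empty band reports the physical lower
   bound 1.0 as a sentinel plus an `empty_band` flag.

## Phantoms

`make_nodule_phantom` digitizes a sphere (optionally perturbed by random
low-order zonal harmonics, `lobulation` ∈ [0, 1]) on an anisotropic grid;
`make_nodule_hu` overlays canonical CT intensities (solid 50 HU,
ground-glass −600, calcification 400, cavity −950, lung background −850,
all configurable). `grow_vessel_tree` places tube branches radially outside
the nodule with controlled starting distances, optional sinusoidal
perturbation (the tortuosity dial), and a minimum angular separation so
tubes never merge; `rasterize_tubes` marks voxel centres within the tube
radius of the centerline (capsule distance at interior joints, flat ends,
so a straight tube encloses πr²L).

Each tree carries a `PhantomTruth`: per band, the number of tubes whose
centerline enters the band, the rasterized in-band volume (analytic sphere
distance at voxel centres), and the analytic mean tortuosity of in-band
centerline segments computed from a densely sampled polyline. Branch
starting distances keep every in-band arc ≥ 3 mm and ≥ 1.5 mm away from
band boundaries, so digitization cannot flip band membership. On 50 random
phantoms the extractor recovers counts exactly, volumes within 10%, and
tortuosity within 0.05 of the analytic truth (typical errors are ~4% and
~0.02).

## Cohort simulation

The study cohort is not public, so `simulate_cohort` draws benign and
malignant groups whose per-feature means/SDs match the published group
moments for the 18 band features and the demographics (age, gender, smoking
status, pack-years, BMI). The published vein rows at 15 mm are mislabelled
"vein10" in the source table; the simulator emits `vein15_*`.

Distributional choices (all with **exact** moment matching):

- counts: negative binomial — the published moments are overdispersed
  (e.g. benign artery5_count 1.67 ± 2.18), which no zero-truncated normal
  can attain;
- lower-bounded continuous features (volumes, Agatston): (shifted) gamma;
- two-sided-bounded features (composition ratios, diameter, tortuosity):
  scaled beta. Tortuosity is bounded to [1, 2]: the lower bound is its
  definition, and pulmonary branch tortuosity beyond ~1.6 (a semicircular
  branch) is already extreme — an unbounded marginal matching the published
  mean ≈ 1.05, SD ≈ 0.15 would emit nonphysical outliers;
- unbounded features (age, BMI, density): normal; binaries: Bernoulli.

Band counts/volumes are built cumulatively (band-10 = band-5 + a
non-negative increment with the moment difference), enforcing within-subject
nesting; increments are feasible because the published SDs rise with band
distance. A Gaussian one-factor copula (level 0.3 by default) correlates
features within a subject; increments stay independent of their own base so
the totals keep the prescribed variance.

CT-derived nodule characteristics have no published moments; the defaults
are this package's own choices (documented in `cohort.NODULE_FEATURES`),
shaped so diameter separates the groups (malignant 17.0 ± 7.5 mm vs benign
8.5 ± 4.0 mm, truncated to the 2.39–39.5 mm study range), calcification
favours benignity, and the 8–20 mm subset holds roughly half the cohort.
Geometry columns (volume, surface area, irregularity, max diameter) are
derived from the simulated diameter with multiplicative noise so the
irregularity identity holds exactly.

`simulate_logit_cohort` is the controlled-effect mode: features from pooled
moments, labels from a logistic model on chosen standardized features. It
drives the parameter-recovery and null experiments.

**What the simulator does not emulate:** real spatial correlation between
nodule size and local vessel density, scanner/segmentation artefacts, and
any distributional shape information beyond two moments. Passing tests
therefore validate the pipeline's correctness and calibration, not the
clinical effect sizes.

## Statistical pipeline

Univariate logistic regressions run on unstandardized features
(coefficients per natural unit, Wald 95% CIs); a helper converts a slope to
the percent change in odds (1 − e^β for β < 0 — e.g. an age slope of −0.12
per year is an 11.3% drop in odds per year). All features are then z-scored
(sample SD, n−1; configurable) and each model family goes through:

1. **LASSO selection** — L1 logistic path over 30 log-spaced penalties,
   penalty chosen by minimum mean CV deviance (stratified 10-fold; 5-fold
   on the 8–20 mm subset); zero-coefficient features dropped. The CV-minimum
   rule (not 1-SE) is the default.
2. **VIF filter** — iteratively drop the largest VIF while any exceeds 5.0;
   ties break lexicographically.
3. **Forward stepwise** — greedy AIC, capped at floor(events/10)
   (one-in-ten rule); skipped when the candidate count already complies.
4. **Final logistic fit** — statsmodels MLE; under complete separation a
   light ridge (α = 10⁻⁴) keeps coefficients finite and p-values are
   reported as NaN.

Selection runs once on the full data by default; stratified k-fold CV then
refits the final logistic model per fold and pools the out-of-fold
probabilities. The AUC is computed on the pooled predictions with a DeLong
95% CI, accuracy at the 0.5 threshold with a Wilson CI. An empty selection
degrades to the intercept-only predictor, reported as AUC 0.5 with a
degenerate CI. Paired models are compared with the DeLong test (placement
values, midrank tie handling) on the pooled out-of-fold predictions of the
same subjects.

The select-once default is deliberately the literal, optimistic procedure:
on pure-noise data its pooled CV AUC sits slightly above 0.5 because the
selection has already seen every label. `nested=True` (CLI `--nested`)
re-runs the whole cascade inside each training fold, giving unbiased
out-of-fold predictions; the nested fold models use a coarser penalty grid
(15 points) and 5 inner folds, which affects runtime, not the absence of
bias. The null-calibration experiment uses the nested mode for exactly this
reason — it is the estimator whose CIs are supposed to cover chance.

Model families: the compartment × band grid (Artery/Vein/Vessel ×
5/10/15/all) plus six integrative sets (demographics, macro-vasculature,
CT-derived nodule, and their unions up to the composite model).

## Importance survey

Three explainers on standardized features: unpenalized logistic regression,
linear SVM (C = 1.0), and an MLP. The MLP's published description ("100
hidden layers") is read as one hidden layer of 100 units — the common
library default; a literal 100-layer network is configurable but not
default. Constant learning rate 0.001, trained to the library's convergence
criterion, seeded.

- **Permutation importance**: mean AUC drop over seeded column shuffles,
  computed on the training table (n is small; a held-out variant is a
  parameter away).
- **Shapley values**: exact, always on the decision scale. Linear models
  use the closed form φ_j = w_j (x_j − b_j) on the margin; the MLP uses
  full enumeration over all 2^p coalitions with background-mean imputation
  on its log-odds output — explaining the probability instead would let the
  sigmoid squash the attributions of the dominant feature on confidently
  classified samples while leaving noise-feature wiggles uncompressed
  (p ≤ 20 enforced; the 18-feature survey is
  2^18 evaluations per explained sample, so the MLP attribution averages
  |φ| over a seeded subsample of rows — 32 by default, 16 in the
  long-running experiments). Local accuracy (Σφ = f(x) − f(background))
  holds to numerical precision by construction.

The six score columns are min-max normalized to [0, 1] (the published
tables contain exact 0.00 entries, which rules out divide-by-max) and
averaged; a constant column is zeroed with a warning.

## Problem sizes in the validation experiments

Chosen as the package's study conditions: 50 phantoms for ground-truth
recovery (≈ 90³ voxel grids at 0.5 mm); n = 2000 cohorts over 25 seeds for
the single-signal selection/importance experiment (PI with 5 repeats, MLP
Shapley on 32 subsampled rows); n = 400 null cohorts over 50 seeds,
evaluating the three band-5/compartment families (Artery5, Vein5, Vessel5)
per seed with nested selection and measuring how often the AUC CI covers
0.5.

## Known limitations

- Skeleton branch decomposition near complex junction clusters (adjacent
  degree ≥ 3 voxels) can split hair-thin branches; phantom trees avoid
  merged junctions by construction, real vasculature may not.
- The tortuosity length estimator is tuned for curvature scales above 2 mm;
  genuine sub-2-mm wiggle is invisible at typical CT resolution anyway.
- Selection runs once on the full table before CV (the literal reading of
  the procedure it reproduces); this is optimistic relative to fold-internal
  selection, which is available via `fit_and_evaluate(..., select=False)`
  composition with external loops but is not the default.
- Group-moment simulation reproduces first and second moments only; any
  conclusion about real-data effect sizes is outside what these experiments
  can show.
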