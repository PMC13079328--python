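# Methods

This note documents the models, conventions and design choices behind
`pvspatial`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Geometry conventions

All volumes are axis-aligned voxel lattices with per-axis spacing in mm
(`VoxelGrid3D`).  World coordinates are `index × spacing`; the rotational
part of a NIfTI affine is ignored, because every within-subject quantity the
pipeline computes (centroids, distances, volumes) is invariant to a rigid
reorientation applied consistently to a subject's coregistered masks.
Subjects whose masks disagree in shape, or in spacing by more than 1e-4 mm
per axis, are rejected (skip-and-log in cohort runs, abort in strict mode);
no resampling is attempted.

Connected components default to 26-connectivity: perivascular spaces are
thin oblique tubules that fragment under face-only adjacency.  Connectivity
is a parameter (6/18/26) everywhere components are formed.  Component ids
are deterministic (ordered by each component's lexicographically first
voxel).  Centroids are unweighted voxel-index means — masks are binary, so
there is nothing to weight by.

## Lesion boundaries and distances

The lesion boundary shell is the mask minus one erosion with the
6-connected cross kernel, with out-of-volume treated as background (brain
masks do not touch the array border in practice, and the convention makes
the contract deterministic).  The shell plus the eroded interior partitions
the mask; this identity is property-tested against a brute-force neighbour
scan.

Each EPVS is represented by its centroid.  Its distance to lesions is the
minimum Euclidean distance from the centroid to any boundary voxel centre.
The reference algorithm expands a cubic (Chebyshev) window around the
centroid's rounded voxel index, starting at radius 1.  A first hit is not
accepted: a voxel inside the window can be Euclidean-farther than one
outside it, so the window keeps growing until the stopping bound proves
exactness.  The bound: a voxel outside radius `r` differs by at least
`r + 1` index steps on some axis, and the centroid lies within half a voxel
of its rounded index, so every outside voxel is at distance at least
`(r + 0.5) · min(spacing)`.  The search stops when the current best is at or
below that bound, guaranteeing equality with the exhaustive minimum — an
equality the acceptance suite asserts with zero tolerance on 1000 random
boundary/centroid pairs including anisotropic spacings.  For cohort runs
the default path builds a KD-tree over boundary voxel centres, which is
exact for the same metric and faster; the two paths are asserted to agree.

Within-lesion membership uses the centroid's nearest voxel index, not
any-voxel overlap, keeping the bin histogram a partition of components; a
within-lesion EPVS is at distance 0.  Distances use voxel centres with no
sub-voxel surface interpolation, matching the voxel-level boundary
construction.  Subjects with no lesion voxels get +infinity distances,
which fall in the >30 mm bin, plus a `has_wml=False` flag so the modelling
layer can include or exclude them; the default includes them, since
excluding lesion-free subjects would bias the distal bins.

Bins are half-open above — (0,5], (5,10], …, (25,30], >30 — so that an
exact 5 mm distance lands in the first bin and the coarse categories
(within = 0 mm, near = ≤5 mm approximating the lesion penumbra, far
= >5 mm) agree with the bin scheme by construction.

## Regional metrics

Five regions: whole brain, white matter, basal ganglia (thalamus, caudate,
putamen, pallidum, accumbens; FreeSurfer aseg colour-table ids by default,
fully overridable), the lesion mask, and brain-minus-lesions.  Regional
EPVS counts intersect the EPVS mask with the region and count components of
the intersection.  This is deliberate and documented: a component straddling
a region border contributes to both regions, and a component split by the
border counts more than once, so regional counts are not a partition of the
whole-brain count.  A centroid-assignment alternative (each component
assigned to the single region holding its centroid voxel) is available via
`assignment="centroid"` and is the rule the distance analysis effectively
uses.  Whether WM/BG masks should exclude lesion voxels is left to the
label source; no exclusion is applied by default.  Volumes are normalized
as percent of intracranial volume.

## Statistical models

- **Counts**: NB2 regression with log link; dispersion α estimated by
  maximum likelihood (statsmodels).  Effects reported as β_exp = exp(β)
  with Wald 95% CIs on the exponentiated scale.  For within-lesion counts,
  where a majority of subjects have none, a zero-inflated NB with an
  intercept-only inflation component is used; nothing in the analysis
  motivates inflation covariates.  ZINB optimization runs a derivative-free
  Nelder–Mead pass to locate the basin followed by BFGS for curvature;
  non-convergence is flagged on every returned term, never silently
  replaced by a different model.  The BFGS default gradient tolerance is
  used: tightening it further changes estimates only past the seventh
  decimal while tripping spurious line-search failures.
- **Volumes**: natural-log outcome, Gaussian GLM (OLS).  "Standardized β"
  here means: z-score the log outcome and all continuous predictors;
  leave binary/categorical indicators as 0/1 contrasts.  Zero volumes are
  excluded (log undefined) and counted in an exclusion report; an ε-offset
  alternative (half the smallest positive observed volume) is available.
- **Covariates**: age and sex enter all adjusted models as fixed
  covariates; APOE/education can be added as sensitivity covariates.  Count
  models carry no exposure offset by default (volumes are ICV-normalized,
  counts are not); a log-ICV offset flag would be the natural extension.
- **Contrasts**: adjacent-stage contrasts are computed by re-levelling the
  reference and reading the coefficient of the later stage, which is
  algebraically the Wald test of the coefficient difference.
- **Multiple testing**: Benjamini–Hochberg step-up, applied within each
  hypothesis family (`family_id`, one family per output table by default —
  the family partition is a configuration choice, not a statistical
  necessity).  The implementation is a dozen lines of numpy and is
  cross-checked against both a literal O(m²) step-up evaluation and the
  statsmodels reference implementation.
- **Diagnostics**: Breusch–Pagan LM test (n·R² of the auxiliary regression
  of squared residuals on the design, χ² reference) for the Gaussian fits.
- **Effect-size labels**: standardized β — <0.1 small, <0.3 medium,
  0.3–0.5 medium-large, ≥0.5 large; β_exp is labelled by direction of the
  count ratio (β_exp = 1 is "no change").

Segmentation agreement: the voxel-wise Dice is the mean over reference
lesions of the Dice between each lesion and the union of predicted
components touching it (missed lesions contribute 0); the lesion-wise Dice
is 2TP/(2TP+FP+FN) over lesion identities with "hit" meaning at least one
overlapping voxel.  Published prose descriptions of lesion-averaged Dice
scores are ambiguous about the averaging order; these two readings are
standard, testable, and documented here so results are interpretable.
Lin's concordance correlation uses population (1/n) moments per the
original definition.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study conditions
under which the pipeline is validated.

Per subject: the brain is an ellipsoid label volume (ICV ≈ 3.6×10⁵ mm³ at
the default 96³ / 1 mm grid) with a white-matter interior, two basal
ganglia blobs and a cortical rim, encoded with aseg-style ids.  Lesions
grow from random WM seed voxels by iterative stochastic dilation (face
neighbours accepted with probability 0.7) to a lognormal target volume
expressed as percent of ICV; group means follow the 0.5–0.8% range typical
of aging cohorts, with σ = 0.8 on the log scale.  A target exceeding half
the WM volume is an error.

EPVS placement density follows λ(d) = 1 + A·exp(−d/τ) over eligible voxels
(WM ∪ BG, outside lesions), where d is the *exact* Euclidean distance
transform to the lesion boundary shell — deliberately a different distance
code path than the analyzer's search, so generator/analyzer agreement is
itself a test.  Defaults A = 4, τ = 5 mm: a five-fold density excess at the
boundary decaying with the penumbra scale.  Each EPVS is stamped as a
1-voxel-thick random-orientation tubule, 3–8 voxels long; voxels that fall
inside lesions are removed so the EPVS and WML channels stay disjoint
except for deliberately placed within-lesion EPVS.

Total per-subject counts are negative binomial (gamma–Poisson, α = 0.5)
with log-mean = intercept (120 at reference) + group offset + 0.15 per
decade of age + 0.1 for male sex + 0.2 per unit of centred lesion
log-volume.  Group offsets (MCI log 1.2, AD log 1.15) and the demographic
distributions (age means/SDs, sex ratios, cohort proportions 55:34:11)
mirror the magnitudes reported for aging/AD cohorts.  Within-lesion counts
are zero-inflated by construction: a structural zero with π = 0.6 —
matching the observed share of subjects with no EPVS inside lesions —
otherwise a zero-truncated Poisson (mean parameter 2) number of short
tubules confined to the lesion mask.  Because the non-zero branch is
zero-truncated, the subject-level zero share equals π up to binomial noise,
a calibration the acceptance suite measures through the full mask pipeline
rather than from the generator's bookkeeping.

Randomness: one master seed, split per subject as
`SeedSequence((seed, subject_index))` feeding a counter-based Philox
generator — cohorts are bit-identical under regeneration and safe to
generate in parallel.

What the generator does *not* emulate: MRI intensities, partial-volume and
segmentation error, realistic cortical folding, ventricles, lesion-growth
biophysics, or spatial correlation between lesion location and EPVS beyond
the distance-decay law.  Passing tests therefore demonstrate that the
pipeline's geometry, bookkeeping and estimators are correct under known
ground truth — not that any particular clinical effect size will replicate
on real images.

## Problem sizes and numerical choices

Validation runs use deliberately modest sizes chosen as a sensible
compute/power trade-off: estimator calibration uses the fast numeric count
simulator (coverage: 200 replicates at 500/group; type-I error: 1000
replicates at 200/group), the zero-share calibration uses 500 subjects at
the default 96³ grid, and the coupling-gradient recovery uses 50 replicates
of 60 subjects at 64³ (distal >30 mm bins can be empty on the smaller grid;
such bins are reported as missing and skipped in the gradient statistic).
Maximum-likelihood fits cap at 200 iterations (500 for the ZINB BFGS
stage); percentage cells round half-up to two decimals to match clinical
table formatting.

## Known limitations

- Distances are Euclidean in world space, not geodesic within tissue; an
  EPVS across a sulcus from a lesion can be "near" it.
- No per-lesion attribution: each EPVS is assigned to its nearest boundary
  anywhere, not to a specific lesion cluster.
- The intersect-then-count regional rule can double-count straddling
  components (documented above; the centroid rule avoids it).
- ZINB estimation is less stable than NB at small n or extreme zero shares;
  results carry a convergence flag that downstream code should respect.
- The demographic-table machinery computes percentage cells only where a
  denominator is supplied or derivable; missingness patterns that cannot be
  reconstructed are left blank rather than guessed.
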