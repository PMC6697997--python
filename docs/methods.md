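# Methods

## The measurement

Each lesion is a pair of 3-D SUV volumes (early ~1 h, delayed ~3 h
post-injection) with one binary mask.  Feature extraction is strictly
voxel-wise:

1. **Quantization.** SUVs are mapped to 128 equal-width bins spanning
   the min–max range *inside the mask* of that volume (each time point
   binned independently).  Voxels outside the mask that fall inside an
   extracted sub-volume are binned with the same lesion-derived edges
   and clamped to [1, 128].  Min–max binning makes every feature exactly
   invariant to affine SUV recalibration (a·SUV + b, a > 0), which the
   tests assert on random phantoms.
2. **Sub-volumes.** A 5×5×5 cube is cut around every mask voxel.  Cells
   beyond the image boundary are flagged invalid; no padding values are
   invented.
3. **Planes.** For each cube, the NGTDM features are computed on the
   single central plane of each orientation (axial / coronal /
   sagittal) and averaged over the planes that yield a defined matrix.
   Averaging over *all* 15 slices instead is available behind
   `TextureConfig(all_slices=True)`; the central-plane reading is the
   default because one value per orientation is the only reading
   consistent with averaging "over the three planes".
4. **Lesion value.** The arithmetic mean over defined voxels.  Voxels
   whose three planes are all ineligible (possible only for lesions
   touching the image border under the strict-interior policy) are
   excluded and counted in `n_undefined`.

### NGTDM conventions

The matrix is built at Chebyshev distance d = 1 (8-connected in 2-D).
Two pixel-eligibility policies exist:

* `strict-interior` (default): a pixel enters only when its full 3×3
  neighborhood is inside the patch and valid — the classical
  definition.  On a 5×5 patch this admits the 9 interior pixels.
* `all-valid-neighbors`: any valid pixel with ≥ 1 valid neighbor
  enters; the neighborhood mean uses the neighbors that exist.  Kept
  switchable because the strict policy discards 16 of 25 pixels of a
  5×5 patch.

Degenerate-input conventions, chosen so a textureless region can never
inject NaN into a lesion average: contrast = 0 when a single gray tone
is present; busyness = 0 when its denominator vanishes; coarseness is
capped at 1/ε for a constant patch.  ε defaults to 1e-8 (far below one
bin-difference unit) and is exposed in the configuration.  N_g in the
contrast normalization counts gray tones present among considered
pixels, not the full 128-bin range.

Busyness is *not* invariant to translating all bin labels by a
constant (its denominator Σ|i·p(i) − j·p(j)| involves the absolute
labels); coarseness and contrast are, and the tests pin down exactly
this asymmetry.

## Statistics

* **ROC.** Trapezoidal AUC (equivalent to the Mann–Whitney pair count
  with ties counted half; asserted against exhaustive pair enumeration).
  Orientation is auto-detected as the direction with AUC ≥ 0.5 — benign
  lesions score *higher* busyness and *lower* coarseness, so both
  orientations occur.  The reported operating point minimizes the
  Euclidean distance to (FPR, TPR) = (0, 1); distance ties break toward
  higher specificity (false positives are the clinical failure mode in
  granuloma-endemic settings), then toward the smaller threshold, so
  the choice is deterministic.  Decision rule: score ≥ threshold ⇒
  malignant after orientation normalization.
* **Rank-sum test.** Average ranks for ties.  Exact two-sided p by a
  dynamic program over doubled ranks (exact even with ties) when the
  pooled sample has ≤ 12 values or on request; otherwise the
  tie-corrected normal approximation with continuity correction.  The
  two agree within 0.01 from ~10 per group (asserted).
* **Cross-validation.** Stratified 11-fold by default.  Combined fold
  sizes are fixed first (116 → six folds of 11, five of 10), then each
  class's remainder is allocated to the largest folds, so both the
  combined ≤ 1 invariant and per-class balance hold — plain per-class
  round-robin can violate the combined invariant by 2.  Per fold, the
  operating point is fitted on the training portion and applied to the
  held-out fold; fold metrics are averaged arithmetically.  A
  single-class test fold is skipped with a warning (cannot occur under
  stratification with ≥ 1 benign per fold).  The corner operating point
  balances sensitivity and specificity, so a signal-free feature
  transfers at ~0.5 accuracy regardless of class imbalance — not at the
  majority-class rate, which only an accuracy-maximizing threshold
  would approach.
* **Reader scores.** Simulated 5-point interpretation scores: a latent
  rank-normal (van der Waerden) standardization of the driving feature
  (delayed busyness) plus Gaussian noise, cut at equal-mass quantiles.
  Rank-normal rather than z-score standardization because lesion
  busyness is heavily right-skewed and a z-score latent lets a few
  extreme lesions dominate the discretization.  Noise sd 0.8 models
  readers consulting the texture values, 1.2 readers without them.

## The phantom generator

No public lesion data accompany this analysis, so cohorts are emulated.
The generator encodes the causal story the discrimination rests on, with
one spatial mechanism per class:

* **Malignant** (default 81/cohort): a single compact Gaussian focus,
  width 1.6–2.6 voxels, early peak SUV from a truncated normal
  11.22 ± 6.24 g/ml on [3, 22].  Delayed: uptake ×1.10–1.40 (tracer
  retention), noise ×1.15, surrounding background washed out ×0.8.
* **Benign** (default 35/cohort): 4–8 sharp foci (width 0.55–0.85
  voxels, relative amplitudes 0.5–1.0) spread through a 4.5–6.5-voxel
  envelope with pairwise separation ≥ 3.6× the effective focus width —
  spatially separated high-uptake regions inside one nodule.  Early
  peak SUV truncated normal 6.94 ± 3.58 g/ml on [3, 14].  Delayed:
  global uptake ×0.85–1.05 (washout/stable) with ±35% per-focus jitter,
  apparent focal definition sharpened (PSF ×0.7), noise ×1.9, and a
  multiplicative fine-grain heterogeneity field (sd 0.15, ~1-voxel
  correlation) — inflammatory tissue reads finer and more irregular
  once early blood-pool activity has cleared.

Shared machinery: 32³ grids at 4.25 mm isotropic spacing; an isotropic
point-spread smoothing of 0.8 voxels (~3.4 mm, approximating an
8-mm-FWHM reconstruction filter); Gaussian noise with sd proportional
to √(local activity) (Poisson-like counting statistics — this, not
uniform noise, keeps high-uptake plateaus from turning into artificial
near-constant patches); a smooth correlated background texture field
(sd 0.4 SUV) standing in for non-uniform lung parenchyma; and a mild
early-only intensity mottle (sd 0.08, both classes) representing the
perfusion-dominated early scan.  The mask is the 12% isocontour of the
noise-free early activity — a generous envelope, as manual nodule
segmentation is — morphologically closed so inter-focus valleys stay
inside, largest component, holes filled.  Masks below 64 voxels trigger
a retry with enlarged foci; generated lesions therefore always pass the
inclusion filters.  SUVmax scale calibration uses truncated normals
matching the malignant/benign moments above rather than broad uniform
ranges, so that SUVmax remains a deliberately *imperfect*
discriminator; with well-separated uniform ranges, SUVmax alone would
dominate and the comparison against the texture features would be
uninformative.

All randomness descends from a single seed through per-lesion spawned
`SeedSequence` streams: any lesion is bit-reproducible independently of
cohort size and generation order.

**What the phantoms do and do not show.**  They reproduce the
*structure* of the clinical contrast — direction of every class
difference, the delayed-image advantage for busyness, SUVmax overlap —
but not PET physics (no scatter, randoms, reconstruction artifacts,
motion, or partial-volume modeling beyond Gaussian smoothing), not
histological diversity, and not reader behavior beyond a noisy monotone
channel.  Passing tests demonstrate that the pipeline recovers planted
effects of realistic geometry and magnitude; they say nothing about
clinical accuracy on real nodules.  Two quantitative caveats: phantom
class separations are larger than those printed for the real cohort
(AUCs ≈ 0.95 vs ≈ 0.87), and the delayed-vs-early gap *ordering* is
robust for busyness but a near-tie for coarseness (the separated-foci
mechanism already expresses the coarseness contrast strongly at the
early time point), so the delayed advantage is asserted only for
busyness.

## Numerical and design choices

* Fold assignment, foci placement and all draws use numpy Generators;
  no global random state.
* Feature tables are written with `float_format="%.12g"`; manifests
  carry no timestamps or output paths, so rerunning a configuration
  reproduces every report file byte for byte (per-stage timing goes to
  a separate `run.log`).
* Volumes are float32 end to end, making the NIfTI round trip lossless;
  the tests require disk-reloaded features to match in-memory ones to
  1e-9.
* The inclusion SUVmax cut is applied to the early scan (the screening
  scan); metabolic volume is the mask voxel count.
* Exact rank-sum enumeration is a counting DP over ranks doubled to
  integers, O(n_a · Σ2r); feasible far beyond the n ≤ 12 auto cutoff.
* Problem sizes in the test suite (32³ grids, 116-lesion cohorts, three
  cohort seeds) were chosen to exercise the full pipeline at the study's
  own scale while keeping a complete run in a few CPU-minutes.

## Known limitations

* 2-D NGTDM on three central planes only; no 26-neighbor 3-D variant,
  no complexity/strength features, no GLCM/GLRLM/GLSZM families.
* No registration between early and delayed volumes: the mask is
  assumed valid for both.
* No partial-volume correction; small-lesion bias is handled only by
  the ≥ 64-voxel filter.
* The 1/ε coarseness cap means a single perfectly constant plane
  dominates a lesion mean; with 128-bin quantization and realistic
  noise this does not occur in generated cohorts (verified empirically
  over hundreds of lesions), but near-noiseless real data could require
  a larger ε.
* DeLong confidence intervals and multiple-testing correction are out
  of scope.
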