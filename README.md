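# ngtdmpet

Texture analysis of dual-time-point FDG-PET for solitary pulmonary
nodules (SPNs).

FDG-avid SPNs are hard to classify: in granuloma-endemic populations,
tuberculosis and other inflammatory nodules take up FDG as avidly as
tumors, so SUVmax > 2.5 g/ml alone produces many false positives.
`ngtdmpet` implements a discrimination pipeline built on
neighborhood gray-tone difference matrix (NGTDM) texture: inflammatory
lesions tend to show *spatially separated* high-uptake regions — high
**busyness**, low **coarseness** — while tumors show compact, coherent
uptake, and the contrast between the two sharpens on delayed (~3 h)
images relative to early (~1 h) ones.

## The features

For a quantized 2-D patch, the NGTDM stores, per gray tone *i*, the
accumulated deviation from the local neighborhood mean,

&nbsp;&nbsp;&nbsp;&nbsp;s(i) = Σ<sub>pixels of tone i</sub> |i − Ā<sub>i</sub>|,

with Ā<sub>i</sub> the mean tone of a pixel's 8-connected neighbors, and
the tone probabilities p(i) over the n pixels entering the matrix.  From
these (N<sub>g</sub> = number of tones present):

* coarseness = [ε + Σ<sub>i</sub> p(i)s(i)]⁻¹
* contrast = [1/(N<sub>g</sub>(N<sub>g</sub>−1)) Σ<sub>i</sub>Σ<sub>j</sub> p(i)p(j)(i−j)²] · [1/n Σ<sub>i</sub> s(i)]
* busyness = [Σ<sub>i</sub> p(i)s(i)] / [Σ<sub>i</sub>Σ<sub>j</sub> |i·p(i) − j·p(j)|], p(i), p(j) ≠ 0

Lesion values follow the voxel-wise scheme: SUVs are binned to 128 gray
tones over the lesion's own min–max range, a 5×5×5 sub-volume is cut
around every lesion voxel, each feature is computed on the central
axial, coronal, and sagittal plane and averaged over the three planes,
and the per-voxel values are averaged over the lesion.

Around the features sits the full study machinery: cohort inclusion
filters (metabolic volume ≥ 64 voxels, early SUVmax ≥ 2.5 g/ml),
retention index, Wilcoxon rank-sum comparisons (exact by enumeration
for small samples), ROC analysis with the operating point nearest the
upper-left corner, stratified 11-fold cross-validation of threshold
transfer, Pearson correlation against simulated 5-point reader scores,
and a dual-time-point lesion phantom generator that stands in for
patient data.

## Worked example

Run a small synthetic study from the shell:

```bash
ngtdmpet run --out demo --seed 7 --n-benign 8 --n-malignant 12 --n-folds 5
```

which prints

```
AUC delayed_busyness: 0.979
AUC delayed_coarseness: 0.969
AUC early_suvmax: 0.771
report bundle written to demo
```

Delayed busyness separates the classes almost perfectly on this small
phantom cohort while early SUVmax — the conventional clinical metric —
is mediocre, the ordering the method is designed to exploit.  The
bundle contains `features.csv` (per-lesion feature table),
`group_comparison.csv` (mean ± SD per class with rank-sum z and p; e.g.
early coarseness 0.225 ± 0.041 malignant vs 0.163 ± 0.023 benign,
p = 0.005), `roc_table.csv` (AUC, threshold, sensitivity, specificity,
accuracy per feature), `cv_table.csv`, `correlations.csv`,
`roc_points.csv`, `exclusions.json` and `manifest.json`.  The manifest
records config, seed and version; rerunning with the same seed
reproduces every table byte for byte.

The same pipeline is available as a library:

```python
import ngtdmpet as m

sample = m.generate_lesion(m.default_config("benign"), seed=1)
feats = m.lesion_features(sample.delayed, sample.mask)
print(feats.triplet)          # coarseness / contrast / busyness
print(feats.suvmax, feats.n_voxels)
```

`ngtdmpet simulate` writes phantom cohorts as NIfTI volumes + masks,
`ngtdmpet extract` computes the feature table from any such directory
(real data works the same way: one early and one delayed SUV volume
plus a 0/1 mask per lesion), and `ngtdmpet analyze` runs the statistics
on an existing feature table.

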