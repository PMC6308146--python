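# npcradiomics

Radiomics and recurrence-pattern analysis for nasopharyngeal carcinoma
(NPC) treated with intensity-modulated radiotherapy (IMRT).

Local-regional recurrence after IMRT is the main mode of treatment failure
in NPC, and most recurrences happen *inside* the high-dose volume —
pointing at radioresistant tumor biology rather than geographic miss. This
package implements, as a tested and reusable library, the two analyses
such a study needs:

1. **Dosimetric recurrence classification.** Given the recurrent tumor
   volume V_recur mapped to the planning dose grid, the fraction of
   V_recur receiving at least 95% of the prescribed dose classifies the
   failure as *in-field* (fraction >= 0.95), *marginal* (0.20-0.95) or
   *out-of-field* (< 0.20), plus cohort tabulation (pattern/site counts,
   time-to-failure statistics). A 20-patient clinical table ships with the
   package.
2. **An MRI radiomics pipeline** that discriminates tumors that later
   recur in-field (IFR) from non-progressing tumors (NPD): isotropic
   resampling (1 mm, tricubic), in-contour gray-level normalization to
   [m − 3s, m + 3s] with 64-level quantization, Laplacian-of-Gaussian
   (σ = 0.5/1.5/2.5 mm) and one-level 3-D wavelet derived images, a
   1117-feature manifest (13 shape + 18 first-order + 74 texture features
   on the original image; 92 on each of 11 derived images), the
   ICC → PCC → Kruskal-Wallis/Benjamini-Hochberg → ROC selection cascade,
   and PCA (≥ 85% cumulative variance) feeding ANN/KNN/SVM classifiers
   evaluated by stratified 10-fold cross-validation with pooled-confusion
   metrics (TP/FP rate, precision, F-measure, MCC, accuracy).

Patient images are not distributable, so the package includes a
first-class synthetic cohort generator: two tumor phenotypes realized as
Gaussian random fields with different physical correlation lengths (coarse
4 mm vs fine 1 mm texture) on a SPAIR-T2W-like 0.65 × 0.65 × 4 mm grid,
perturbed second-observer contours for reproducibility analysis, and dose
cases with an exactly known isodose-coverage ground truth.

The texture machinery computes the five standard 3-D matrix families —
GLCM and GLRLM (13 directions, distance 1, per-direction features
averaged), GLSZM (26-connected zones), GLDM (26-neighborhood, zero
tolerance) and NGTDM (3 × 3 × 3 neighborhood) — on a fixed 1..64
gray-level axis, each validated against independent brute-force oracles.

## Worked example

```sh
python examples/05_classification.py
```

runs the full chain on the default synthetic cohort (11 IFR vs 16 NPD
cases, seed 3) and prints:

```
significant features: 50
PCA: 11 components reach 85.39% cumulative explained variance
model   TP rate  FP rate    MCC  accuracy
ANN       1.000    0.000  1.000     1.000
KNN       1.000    0.000  1.000     1.000
SVM       1.000    0.000  1.000     1.000
```

50 features survive the reproducibility/redundancy/significance cascade;
11 principal components explain ≥ 85% of their variance; with the default
well-separated texture scales all three classifiers label every held-out
case correctly. Shrinking the class contrast (`texture_scale_ifr` closer
to `texture_scale_npd`, higher `noise_sd`) degrades these numbers
smoothly. The other examples cover simulation, single-case extraction,
dose-based recurrence classification and the selection cascade; the same
steps are scriptable through the thin `npcrad` CLI
(`simulate | extract | classify-recurrence | run-all | report`).

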