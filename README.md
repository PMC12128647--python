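# spermshape

Fourier harmonic amplitude (FHA) analysis of sperm nuclear shape and
discriminant prediction of ram fertility.

Sperm head shape reflects chromatin packaging, and subtle shape differences
track male fertility in several species. This package re-implements, end to
end, the image-analysis pipeline used to discriminate adequate-fertility
(AF) from low-fertility (LF) rams from Hoechst-stained sperm nucleus
images: fluorescence nucleus segmentation, radial Fourier shape
descriptors, ImageJ-style morphometrics, and a stepwise linear-discriminant
fertility classifier with leave-one-out cross-validation. Because no image
data are published for this system, the package includes a first-class
synthetic-data generator that renders realistic nucleus images and cohorts
with known ground truth, so every stage is testable.

It is aimed at andrology/reproductive-biology groups doing computer-assisted
sperm morphometry, and at method developers who need a fully synthetic,
ground-truthed benchmark for contour descriptors and small-n discriminant
models.

## The method

A closed nucleus contour is expressed in polar form about its area centroid
and fitted by trigonometric regression with a truncated Fourier series

```
r(θ) ≈ c0 + Σ_{k=1..5} (a_k cos kθ + b_k sin kθ)
```

The shape descriptors are the harmonic amplitudes

```
HA0 = c0 (mean radius, μm),   HA_k = √(a_k² + b_k²)   (k = 1..5)
```

HA0 tracks overall size, HA1 anterior curvature, HA2 head elongation, and
HA3–HA5 posterior tapering; amplitudes are rotation-invariant because the
modulus absorbs phase. Per ram (~100 sperm), each amplitude is summarized by
its mean, variance, skewness and kurtosis, joined with eleven ImageJ-style
morphometrics (area, perimeter, circularity, aspect ratio, roundness,
solidity, and gray-level mean/SD/median/skewness/kurtosis) into a 35-feature
vector. Rams are labeled AF/LF by thresholding conception rates at one
population SD below the mean, and a two-group linear discriminant with
stepwise Wilks-lambda variable selection (partial-F entry/stay levels 0.15)
is evaluated by leave-one-out cross-validation, reported as sensitivity
(AF correct), specificity (LF correct) and overall error rate.

## Worked example

```python
import numpy as np
from spermshape import synth, discriminant, fha

# 1) one synthetic nucleus: truth vs fitted amplitudes
params = synth.sample_shape_params("AF")
h = synth.sample_nucleus_harmonics(params, 1, rng_seed=0)[0]
fit = fha.harmonics_from_trace(h.to_polygon(720))
print("true HA:", np.round(h.amplitudes, 3))
print("fit  HA:", np.round(fit.amplitudes, 3))

# 2) reference-scale cohort (47 AF + 9 LF rams, 100 sperm each)
cohort = synth.generate_cohort(47, 9, 100, rng_seed=11, detail="summary")
X = cohort.feature_matrix()
features, labels = X.drop(columns=["group", "n_sperm"]), X["group"]
model = discriminant.StepwiseLDA().fit(features, labels)
print("selected:", model.selected_features_)
print(f"canonical correlation: {model.canonical_correlation_:.3f} (p = {model.p_value_:.2g})")
cv = discriminant.loo_crossvalidate(features, labels, features=model.selected_features_)
print(f"LOO: sensitivity {cv.sensitivity_pct}% ({cv.af_correct}/{cv.af_total}), "
      f"specificity {cv.specificity_pct}% ({cv.lf_correct}/{cv.lf_total}), "
      f"overall error {cv.overall_error_pct}%")
```

prints

```
true HA: [2.864 0.022 0.946 0.056 0.134 0.019]
fit  HA: [2.864 0.022 0.946 0.056 0.134 0.019]
selected: ['ha2_mean', 'intensity_mean', 'ha4_kurt', 'ha3_kurt', 'intensity_kurt']
canonical correlation: 0.646 (p = 4.1e-05)
LOO: sensitivity 83.0% (39/47), specificity 66.7% (6/9), overall error 19.6%
```

The fitted amplitudes match the generator's truth to printed precision
(fitting the exact contour is an identity up to polygon discretization).
Stepwise selection leads with mean HA2 — head elongation, the feature the
cohort is designed to separate on — plus mean intensity; the model is
significant and the cross-validated confusion table shows the classifier's
operating point. At this seed the cohort happens to land exactly on a
39/47, 6/9 confusion split; other seeds give overall errors in roughly the
7–20 % range.

The same run is available from the shell:

```bash
spermshape simulate --af-rams 47 --lf-rams 9 --sperm 100 --seed 42 --outdir sim/
spermshape segment --image field.tif --pixel-size 0.11 --outdir seg/
spermshape fha --traces seg/traces.csv --out fha/
spermshape classify --features features.csv --fertility fertility.csv --out results/
spermshape run --outdir results/        # all stages on a synthetic cohort
```

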