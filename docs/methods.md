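# Methods

This note documents the models, parameter choices and numerical decisions
behind `spermshape`, in the order data flows through the pipeline.

## Shape model and FHA estimation

A nucleus contour is a star-shaped closed curve written in polar form about
its area centroid, r(θ), and approximated by a truncated Fourier series with
K = 5 harmonics. The estimator is ordinary least squares of the sampled
radii on {1, cos kθ, sin kθ}; with equally spaced angles this coincides with
the discrete Fourier transform of the radius samples, which the test suite
uses as an independent oracle. Reported descriptors are the amplitudes
HA0 = c0 and HA_k = √(a_k² + b_k²); amplitudes rather than signed
coefficients are the features, making them rotation-invariant (phase is
retained internally only for shape averaging). HA0 is identified with the
constant regression term — the mean radius in μm — which is consistent with
the ~2.85 μm scale of the reference amplitudes given the ~28 μm² nucleus
area.

Resampling uses M = 128 equally spaced angles (far above the 2K + 1 = 11
minimum; aliasing of smooth head contours is negligible). Radii come from
exact ray/polygon intersection against the area centroid; when a ray
crosses the boundary more than once the farthest crossing is used and the
profile is flagged non-star. A centroid outside the polygon is an error.
The polar origin matters: harmonic amplitudes are only well-defined in the
centre-of-mass frame, so the generator re-expresses every sampled shape in
that frame before it becomes ground truth (see below).

Per-ram dispersion uses the unbiased variance, adjusted Fisher–Pearson
skewness and unbiased excess kurtosis (SAS conventions). Zero-variance
amplitudes report skewness/kurtosis of 0 with a degenerate flag.

**Average shape.** Shapes are aligned by exact polygon moments (computed in
closed form by triangle decomposition): centroid to the origin, major
principal axis horizontal, the anterior end oriented to +x by the sign of
the third moment along the axis, and an optional reflection so the signed
skew along the minor axis is non-negative. Because the moments are exact,
alignment is exactly equivariant under rotation of the input, and the
radii are queried on the *original* polygon along rotated rays (no
intermediate resampling), so a shape and its rotated copy average to the
shape itself to machine precision. Near-circular shapes give an alignment
warning and an arbitrary orientation.

## Segmentation

Nuclei are detected on the negated Laplacian-of-Gaussian response
(σ = 0.3 μm, about the edge scale; it also suppresses shot noise). The
default threshold policy is *Otsu-seeded zero-crossing*: Otsu's threshold
on the response selects significant bright components, and each component's
boundary is then taken at the response zero-crossing, which for a blurred
step edge sits on the true boundary. A plain Otsu level (available as
`"otsu_level"`) erodes the contour by a sizeable fraction of the blur
width and is kept only for comparison. Holes are filled; a constant image
yields an empty mask.

QC gates: 8-connected components outside 10–80 μm² (around the ~28 μm²
nominal nucleus), touching the image border, with solidity < 0.92, or with
area > 1.6× the in-image median are rejected with an explicit reason
(`too_small`/`too_large`/`border`/`overlap`). The overlap rule automates
what was originally a manual deletion step; a manual-rejection label list
is retained in the QC report. All segmentation constants are package
choices validated against synthetic ground truth only (the original
macro's constants are unpublished).

Perimeters are traced through boundary-pixel centers with 8-connected
Moore border following (Jacob's stopping criterion), converted to
Cartesian μm with y up and counterclockwise orientation. Chain-code length
(1 axial, √2 diagonal, optional ×0.948 corner correction) is the trace's
native length measure.

**Digitization corrections.** Two systematic rasterization biases are
corrected on analytic grounds (decided before any recovery experiment):
(1) boundary-pixel centers sit about half a pixel inside the continuous
contour, so the FHA path adds pixel_size/2 to every sampled radius —
without it HA0 is biased by ≈ −0.04 μm at the default 0.11 μm/px;
(2) raw chain-code lengths overestimate smooth boundaries by ≈ 5 %, so
morphometric perimeters default to the length of the marching-squares
contour simplified by Ramer–Douglas–Peucker at one-pixel tolerance, which
is within ~1 % for smooth outlines while recovering polygonal sides
exactly (a rasterized disk then measures circularity ≈ 0.99 and a square
≈ 0.80). The chain-code variants remain selectable.

## Morphometrics

Feature definitions follow the ImageJ User Guide: area is pixel count ×
pixel_size²; the fitted ellipse comes from central second-order moments
(major/minor = 4√(λ/A)); aspect ratio = major/minor; roundness =
4A/(π·major²); solidity = area / convex-hull area; circularity =
4πA/perimeter², clamped at 1.0 on coarse rasters. Intensity statistics are
computed over member pixels only; SD uses the n−1 denominator and
skewness/kurtosis the biased moment estimators with kurtosis reported as
excess — deliberately different conventions from the per-ram amplitude
moments, matching each tool's native definitions.

## Synthetic cohorts: what is emulated

The generator encodes the reference study conditions for Merino rams:
47 AF and 9 LF rams with 100 analyzed nuclei each; group-mean amplitudes
(HA0–HA5) for each fertility group with head elongation the chief
separator (HA2 0.905 vs 0.872 μm); nuclear gray levels ≈ 99 (AF) vs
≈ 111 (LF) on an 8-bit scale; and conception rates with group means
95.1 % and 79.7 %, population mean 89.0, SD 6.6, cutoff 82.4.

**Dispersion split.** Published spreads are SEMs of group means, so a
hierarchical model is imposed: between-ram SD = SEM × √47 and within-ram
per-sperm SD = SEM × √100, both taken from the 47-ram AF column for *both*
groups — the 9-ram LF SEMs mostly reflect group size, not sperm biology,
and importing them would let dispersion features separate the groups
trivially. Under this split the expected two-sample t for mean HA2 across
the default cohort is ≈ 2.2, a borderline signal consistent with the
reference effect, and mean HA2 is the strongest single discriminator
(typical canonical correlations 0.6–0.75 and LOO errors 7–20 %, against a
permuted-label baseline around 40–45 % with equal priors). Because the
signal is borderline by design, stepwise selection retains mean HA2 in
only a modest majority of seeds (~11/20); this is a property of the
emulated conditions, not a tuning failure.

**Shapes.** Per-sperm amplitudes are Gaussian draws (reflected at zero for
k ≥ 1) with canonical phase zero per harmonic — anterior/posterior
asymmetry enters through HA1/HA3 — jittered by N(0, 0.25 rad). Each raw
contour is re-centred by iterated shift-and-refit until its area centroid
is at the polar origin (< 1e-10 μm, typically < 10 iterations on a 256-
point grid); the stored truth coefficients therefore describe the rendered
contour exactly, and fitting the exact contour recovers them to < 1e-12.
Re-centring is why truth HA1 is emergent (order 0.02–0.06 μm from
even–odd harmonic coupling) rather than the raw sampled value: a nonzero
first harmonic largely trades off against translation.

**Rendering.** Pixel size defaults to 0.11 μm/px (≈ 40× objective with a
1.25× magnifier; the original calibration is unpublished, so this is an
assumption). Nuclei are rasterized by the exact center-inside rule, filled
at the sperm's intensity modulated by a smooth multiplicative chromatin
texture (relative SD 0.15, correlation length 0.5 μm — chosen so the
within-nucleus gray-level SD lands on the published ~18 at mean ~99 and
~20 at mean ~111), blurred with a Gaussian PSF (σ 0.15 μm, typical
widefield), and exposed with Poisson shot noise plus Gaussian read noise
(SD 2 gray levels) over a background of 10, quantized to 8 bits (12/16
configurable). The phase-like channel is a contrast-inverted, halo-blurred
rendering used only for overlay QC. Fields place nuclei at random
non-overlapping poses (bounding-circle exclusion); a requested overlap
fraction is placed onto existing nuclei with verified mask intersection
and both partners flagged, to exercise rejection QC.

**What the generator does not emulate**, hence what passing tests cannot
show about real data: optical aberrations and non-Gaussian PSF tails,
photobleaching, staining heterogeneity beyond the smooth texture field,
debris and non-sperm objects, tails/midpieces, and any true biological
covariance between shape and intensity (groups differ in both, but within
a ram the two are sampled independently). Summary-level cohorts compute
geometric features analytically from the true contours (area in closed
form, perimeter and moments by quadrature, solidity via convex hull) and
intensity statistics from the renderer's noise model without rasterizing;
the rendered route reproduces these within measurement error.

## Discriminant analysis

The fertility cutoff uses the population (ddof = 0) SD, matching the
reference arithmetic 89.0 − 6.6 = 82.4; rams exactly at the cutoff are AF.
Group comparisons use pooled-variance Student's t (Welch by flag).

Stepwise selection standardizes features internally and alternates forward
entry (smallest partial Wilks-lambda p-value, if below 0.15) with backward
elimination (largest p-to-stay above 0.15), the SAS default levels; for
two groups the partial F equals the extra-sum-of-squares F of the
equivalent regression on the group indicator, which is the test oracle.
Candidates with R² > 0.999 against the selected set are skipped
(collinearity guard), and max_rounds = 20 bounds the search. Note that
greedy best-of-k entry at a lenient 0.15 level admits several noise
variables on null data (median ≈ 7 from 38 candidates at n = 56); an
empty selection is a valid outcome and yields a majority-class null model
in reports.

The discriminant itself is the classical two-group linear rule with pooled
within-group covariance and SAS-style per-group score functions; priors
are equal by default (proportional by flag) and posterior ties go to the
majority class (AF). The canonical correlation is √(1 − Λ) — identical to
the correlation between the discriminant score and group membership — and
the model p-value is the exact Wilks-lambda F transform with
(p, n − p − 1) degrees of freedom. Leave-one-out cross-validation refits
the discriminant n times on a fixed feature set; folds with a singular
pooled covariance (or a fold that empties a group) are flagged and counted
as errors. Sensitivity is AF-correct/AF-total and specificity
LF-correct/LF-total; the overall error is (FP + FN)/n, reported to one
decimal and as the rounded integer percent.

## Known limitations

- The reference per-ram data are unpublished: fitted coefficients, the
  reported canonical correlation (0.747) and exact confusion tables are
  not reproduction targets, only scales and arithmetic are.
- The polar series requires star-shaped contours; strongly bent or folded
  heads would need an elliptic-Fourier treatment, which is out of scope.
- Selection-then-CV shares the feature list across folds (as in the
  original SAS workflow); selection inside each fold would give more
  conservative error estimates.
- Problem sizes in the test suite are scaled to what a laptop-class CPU
  runs comfortably: the full rendered cohort (5,600 nuclei) appears once,
  stepwise-selection frequency uses 20 summary-level cohorts, and the
  permuted-label baseline uses 20 permutations.
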