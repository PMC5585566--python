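# Methods

This note documents the models, algorithms, parameter choices and
numerical conventions behind `octeb`, and what its synthetic benchmark
does and does not demonstrate.

## Coordinate and intensity conventions

Images are 2-D arrays with row 0 anterior (top) and columns as A-scans;
all indices are 0-based. Intensities are normalized to [0, 1] on
ingestion (BT.601 luminance for color inputs; 8/16-bit ranges divided by
their maximum). Boundary traces are real-valued row positions, one per
column; rasterization rounds half-up (10.5 → 11). Convolution and
filtering use edge replication at borders throughout, so results are
bit-stable and free of wrap-around artifacts.

## The phantom generator

A phantom is a stack of `n_boundaries + 1` constant-reflectivity bands.
Boundary k is its mean depth plus a smooth zero-mean perturbation:
per-column white noise smoothed by a Gaussian kernel of width
`undulation_smoothness` (default 40 columns) and rescaled so its maximum
absolute excursion equals `undulation_amplitude` (default 4 px). Pairs of
adjacent boundaries closer than `min_gap` (default 8 px) are pushed apart
symmetrically and iteratively — a deterministic projection that always
terminates for feasible specs, unlike rejection sampling. The band
containing a pixel starts at the rounded boundary row, so the rasterized
edge mask coincides exactly with the first row of each intensity change.

Speckle is modeled as unit-mean multiplicative gamma noise: each pixel is
multiplied by an independent Gamma(L, 1/L) variate. This is the standard
fully developed speckle model for L-look coherent imaging; the default
L = 16 (contrast ratio 1/√L = 0.25) represents a moderately averaged
clinical B-scan. No published noise level exists for the imaging setup
the defaults emulate, so L is an explicit, documented calibration knob of
the generator, not a measured value.

Default geometry is 200 × 400 px with six boundaries at mean depths
(25, 55, 85, 110, 135, 170) and band reflectivities
(0.08, 0.62, 0.30, 0.55, 0.22, 0.75, 0.12) — dark vitreous, bright
NFL, alternating inner layers, bright photoreceptor/RPE complex, dark
choroid — giving both edge polarities in realistic proportion. The ROI
is the inclusive ILM-to-RPE band per column.

What the phantom does **not** model: vessel shadows, motion artifacts,
depth-dependent signal roll-off, pathology, and anatomically calibrated
reflectivities. Benchmark results on phantoms therefore demonstrate
correctness of the pipeline and the *relative* behavior of detectors
under layered-plus-speckle conditions; absolute metric values on clinical
images will differ.

## Detectors

**Canny.** Gaussian smoothing at σ, central-difference derivatives,
root-sum-of-squares magnitude normalized to max 1, direction
atan2(∂row, ∂col). Nonmaximal suppression compares each pixel with its
two neighbors along the 45°-quantized gradient direction; the comparison
is strict ahead and non-strict behind, which resolves plateau ties to one
side and keeps ridges one pixel thick. Hysteresis keeps pixels above T2
plus any pixel above T1 that is 8-connected to one through candidates.
Defaults σ = 3, T1 = 0.005, T2 = 0.1.

**Two-pass.** The vertical derivative-of-Gaussian kernel
L(x, y) = −p·x/(πσ²)·e^{−(x²+y²)/(2σ²)} (x = vertical offset) is
evaluated at integer offsets on a (2r+1)² grid with r = ⌈3σ⌉ and applied
by correlation. With p = +1 the positive response peaks at
bright-above-dark transitions; p = −1 at dark-above-bright. Each pass
clips to its positive part, normalizes to max 1, thins per column
(vertical NMS with the same asymmetric tie-break), applies hysteresis
(T1 = 0.005, T2 = 0.15), and the final map is the union of the passes.
The kernel is odd in x, so the two responses are exact negations; the
p-roles swap exactly under vertical image flip at response level. Binary
maps can differ at exact response ties after flipping, because a
one-pixel-thin NMS necessarily breaks ties asymmetrically; on images with
continuous-valued noise, ties have measure zero and the map-level
identity holds.

**EdgeFlow.** Directions are discretized as θ_k = 2πk/n (n = 8 by
default, even so θ and θ+π are both on the grid). Per attribute
a ∈ {intensity, texture}: the energy E_a(s,θ) is the magnitude of the
directional derivative-of-Gaussian response at scale σ; the
predictive-coding error is |S(s + d·u_θ) − S(s)| with S the σ-smoothed
channel and d = 4σ; and P_a(s,θ) = Err_a(θ)/(Err_a(θ) + Err_a(θ+π)),
with P = 0.5 where the denominator vanishes, so P(θ) + P(θ+π) = 1 by
construction. The texture attribute uses the energy images of a Gabor
bank (4 orientations × 2 frequencies {0.1, 0.2} cycles/px, kernel width
tied to σ) in place of the intensity image. Energies and probabilities
are pooled with weights ω (default 0.5/0.5; both attributes are always
computed, so a zero weight contributes exactly nothing). The flow
direction Θ(s) maximizes the half-plane sum of P (ties to the smallest
angle), the vector F(s) sums E·e^{jθ} over [Θ, Θ+π), and propagation
iteratively hands each vector to the 8-neighbor nearest its direction
whenever that neighbor's current direction differs by < 90°, until a
fixed point or `max_iterations` (default 30; non-convergence is reported,
not fatal). Edges are marked on 4-neighbor pairs whose stable vectors
subtend > 90° and both point across the shared border; the pair strength
(sum of magnitudes) is credited to the pixel with the larger energy, and
the strength map is normalized and thresholded by hysteresis
(T1 = 0.005, T2 = 0.1 — not published for this detector; they mirror
Canny's and are configurable).

All three detectors return an empty map on constant input (responses
below 1e-12 of full scale are treated as zero rather than normalized,
which would only amplify roundoff).

## Metrics

Evaluation is restricted to the ROI; detected pixels outside it are
ignored. Exact matching counts TP/FP/TN/FN against the rasterized truth;
d(i) for the FOM is the Euclidean distance from detected pixel i to the
nearest ground-truth pixel (a per-column variant is available — the two
differ only where a neighboring A-scan's boundary is closer than the
pixel's own). FOM of an empty detection is 0, as is the redefined FPR.

MLD searches ±3 px along each A-scan: ground-truth pixels with empty
neighborhoods are excluded from the outer mean (counting a miss as 0
would reward non-detection), and MLD is reported as NaN when every
neighborhood is empty.

Adjusted matching (radius 2 px per column by default): TP_ADJ counts
ground-truth pixels with at least one detection in their column window —
capping TP_ADJ at N_I, so no ground-truth pixel is credited twice —
while FP_ADJ counts detections matching no window. TN_ADJ = TN, which
the adjustment cannot affect. The adjusted distance of a detected pixel
is min(exact distance, column residual), which makes
FOM_ADJ ≥ FOM, TPR_ADJ ≥ TPR and ACC_ADJ ≥ ACC identities of the
implementation. FPR_ADJ = FP_ADJ/N_I by definition; because its
denominator (N_I) differs from FPR's (N_A), FPR_ADJ ≤ FPR is an
empirical regularity of reasonable detectors rather than a theorem — a
detector that over-detects wildly (N_A ≫ N_I) can break it, and one
Canny run on a phantom seed outside the default benchmark does. All four
inequalities hold on every run of the default benchmark.

MLD uses a ±3 px window while the adjusted metrics use ±2 px: the two
tolerances serve different purposes (localization measurement vs
presence crediting) and are configured independently.

## Benchmark and statistics

The default benchmark is 8 phantoms (seeds `base_seed + 0..7`) at the
default spec, 3 × 3 median prefilter, and the three detectors at the
defaults above — sizes chosen to mirror a realistic small reader study
while keeping a full run under a minute on one core. Summaries report
mean ± sample sd (n−1). Detector pairs are compared per metric with
one-sided two-sample t-tests; the Student pooled-variance form is the
default ("two-sample t-test" in its classical reading), Welch and paired
variants are switches. Directions follow each metric's polarity (larger
is better for FOM/TPR/ACC and their adjusted forms; smaller for FPR,
FPR_ADJ, MLD). No multiple-testing correction is applied, matching the
protocol this mirrors. The report flags — but does not enforce — the
expected mean-FOM ordering two-pass > EdgeFlow > Canny, since phantom
statistics need not perfectly mirror clinical imagery.

On the default conditions the ordering does hold, with the two-pass
method ahead of Canny on FOM at p < 1e-10 and EdgeFlow intermediate:
intensity-gradient structure dominates texture structure along layered
boundaries, and the polarity-specific vertical kernel is better matched
to near-horizontal boundaries than an isotropic gradient.

## Known limitations

* EdgeFlow internals beyond the pooled-energy/probability/vector
  equations (prediction offset, Gabor bank, error-ratio probabilities)
  follow the originally published technique but involve free choices;
  they are isolated behind `EdgeFlowParams` so they can be varied.
* The propagation fixed-point test is exact equality of the vector
  field; cyclic states are theoretically possible and are cut off by
  `max_iterations` with a non-convergence flag.
* Phantom realism limits are listed above; absolute metric levels on
  clinical B-scans will differ from phantom levels, and parameter
  re-tuning (especially thresholds, which are relative to each image's
  peak response) may be needed for other instruments or scan protocols.
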