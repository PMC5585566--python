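# octeb — edge-detector evaluation for retinal OCT B-scans

Retinal layer thickness measurement from optical coherence tomography
(OCT) depends on finding the layer boundaries — ILM, NFL-GCL, IPL-INL,
OPL-ONL, ONL-IPS, RPE-choroid — in speckle-corrupted B-scans. Different
families of edge detectors (intensity-gradient versus texture based)
behave very differently on this kind of image, and choosing between them
requires a ground-truth evaluation protocol, not visual impressions.

`octeb` is that protocol as a tested, reusable pipeline, aimed at
researchers benchmarking boundary detectors for OCT segmentation:

* **Phantoms** — a synthetic layered-retina generator: 5–7 stacked bands
  of distinct reflectivity separated by smooth, undulating, non-crossing
  boundaries, corrupted by unit-mean multiplicative gamma speckle, with
  exact boundary traces, edge masks, and the ILM–RPE region of interest.
  Every downstream stage is testable with no proprietary data.
* **Detectors** — three boundary detectors producing binary edge maps:
  the Canny detector (Gaussian smoothing, gradient magnitude, nonmaximal
  suppression, hysteresis; σ = 3, T1 = 0.005, T2 = 0.1); the **two-pass**
  method built on the vertical derivative-of-Gaussian kernel

  L(x, y) = −p·x/(πσ²)·exp(−(x² + y²)/(2σ²)),

  applied with both polarities p = ±1 to catch bright-above-dark and
  dark-above-bright transitions (σ = 3, T1 = 0.005, T2 = 0.15); and
  **EdgeFlow**, which pools intensity and Gabor-texture edge energies
  E(s,θ) with predictive-coding probabilities P(s,θ)
  (ω(intensity) = ω(texture) = 0.5), forms the vector
  F(s) = Σ_{Θ≤θ<Θ+π} E(s,θ)e^{jθ}, and propagates the vectors until
  opposite flows meet at boundaries.
* **Metrics** — Pratt's figure of merit
  FOM = 1/max(N_I, N_A) · Σᵢ 1/(1 + αd²(i)) with α = 1/9; TPR = TP/N_I;
  the redefined FPR = FP/N_A; ACC = (TP+TN)/N; mean localization
  deviation (MLD) with a ±3 px per-A-scan search window; and the
  shift-adjusted family FOM_ADJ, TPR_ADJ, FPR_ADJ = FP_ADJ/N_I, ACC_ADJ
  that credits detections within a ±2 px per-column neighborhood, since a
  small constant boundary shift does not bias thickness measurements.
* **Benchmark** — runs detectors over an image set, tabulates the nine
  metrics per image inside the ROI, summarizes mean ± sd per detector,
  and compares detectors with one-sided two-sample t-tests (Student
  pooled-variance by default).

## Worked example

The numbered scripts under `analysis/` run the study end to end. On one
default phantom (seed 0, 200 × 400 px, 6 boundaries, 16-look speckle,
3 × 3 median prefilter), `python analysis/02_detect_edges.py` prints:

```
detector       px    fom    tpr    fpr    mld  tpr_adj    time
canny        3960  0.597  0.506  0.689  0.482    0.975   0.01s
twopass      2496  0.917  0.507  0.500  0.479    0.975   0.03s
edgeflow     2404  0.805  0.485  0.424  0.431    0.840   0.65s
```

Read: the two-pass method places nearly the right number of edge pixels
(2496 vs 2400 true ones) with the highest FOM 0.917, i.e. its detections
sit closest to the true boundaries; Canny over-detects (3960 px, FPR
0.689) because speckle-induced gradients inside the layers survive its
thresholds; EdgeFlow is clean but misses more boundary pixels per column
(TPR_ADJ 0.840) and is ~20–60× slower. `python analysis/03_benchmark.py`
repeats this over 8 phantoms and confirms the impression statistically:

```
  FOM  twopass > canny   : t= 19.965  p=5.504e-12
  FOM  twopass > edgeflow: t= 13.153  p=1.429e-09
  FOM edgeflow > canny   : t= 15.130  p=2.270e-10
mean-FOM ordering twopass > edgeflow > canny: holds
```

The same pipeline is scriptable on real images through the CLI:
`octeb phantom`, `octeb detect --method {canny,twopass,edgeflow}`,
`octeb evaluate`, and `octeb bench --config config.yaml`.

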