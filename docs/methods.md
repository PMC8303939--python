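# Methods

## PRFS temperature model

The reconstruction treats every scan's phase volume as

φₙ = φ₀₀ + γαB₀TE·ΔT(n) + d(n) + a(n) + ε

where d(n) is a slowly varying B₀-drift phase, a(n) a susceptibility
perturbation near gastrointestinal air, and ε Gaussian phase noise.
Decoding uses the wrapped difference angle(exp(i(φₙ − φ₀₀))) divided by
γαB₀TE, so the contract is wrap-safe even though, with the default PRF
coefficient, the per-°C phase increment (−7.664 × 10⁻³ rad/°C) is far from
the branch cut; wrapping is exercised only through the drift and artifact
terms.

**The PRF coefficient.** The default is α = −0.001 ppm/°C, with the
conventional literature value −0.01 ppm/°C selectable as
`core.ALPHA_LITERATURE_PPM_PER_C`. The tenfold-smaller default makes the
phase-to-temperature gain 1/(γαB₀TE) ≈ −130 °C/rad, i.e. even small phase
noise is amplified strongly; all defaults below are chosen under that
gain. Every stage uses whichever α the `PRFSConstants` carries, so results
are consistent under either choice.

## Processing chain

Stages advance strictly `uncorrected → snr_masked → drift_corrected →
filtered`; invalid voxels are excluded from all fits and means and never
interpolated.

* **Low-SNR masking** invalidates a voxel when |ΔT| deviates from the mean
  of its 8 in-plane neighbors (center excluded, borders use available
  neighbors) by more than 3 °C. Excluding the center makes a lone spike
  detectable against a flat background.
* **Drift correction** fits, per scan time and per slice independently, a
  2-D polynomial of total degree ≤ 2 (6 coefficients on coordinates
  normalized to [−1, 1]) to ΔT at valid fat voxels and subtracts the
  surface from the whole slice. Because the design includes a constant
  term, the mean residual over the fitted fat voxels is zero to machine
  precision, and a second application changes nothing (idempotence).
  Slices with fewer fat voxels than coefficients fall back to a lower
  order with a warning; slices with no valid fat are left uncorrected and
  flagged. A caveat worth knowing: fitting a quadratic on a thin annulus
  (the subcutaneous fat ring) leaves the constant and the r² terms nearly
  collinear, so the extrapolated surface at the slice center carries
  amplified noise variance. The default ring (≥ 1.2 cm thick, elliptical)
  keeps this manageable, but very thin fat rings would not.
* **Outlier exclusion** invalidates voxels with |ΔT| > p. The threshold is
  either the fixed clinical default p = 7 °C or optimized on a 0.1 °C grid
  over [0, 20] °C by minimizing G(p), the mean over (scan, location) pairs
  of |surviving-ROI mean − aligned probe mean|; the smallest p attaining
  the minimum wins. Absolute ΔT is used (the filter targets magnitude
  outliers). A pair whose ROI empties at some p is skipped for that p; to
  prevent pre-heating maps (truth ≈ 0, probe ≈ 0) from dominating small-p
  objectives once the heated terms are skipped, the pipeline restricts the
  objective to scans after RF-on. On synthetic sessions, whose ROI
  temperatures reach only 1–3 °C, the optimum typically lands at 1–4 °C —
  the same mechanism, at the synthetic dynamic range, that yields 7 °C on
  clinical data reaching ~44 °C absolute.
* **ROI averaging** uses circular ROIs of diameter 1.37 cm per probe-bearing
  slice, rasterized by voxel-center-in-circle. This rule is reproducible
  and grid-independent but biases the area slightly low (1.37 cm² at
  matrix 128, 1.41 cm² at 256, vs the nominal 1.47 cm²); at matrix 64 an
  ROI may be a single voxel. Empty ROIs yield NaN, never a fabricated value.

**Probe-to-scan alignment.** Probe mapping cycles (every 300 s) are paired
to the scan whose midpoint (start + 83/2 s) is nearest the cycle start,
requiring the offset ≤ 150 s; the per-location probe value is the mean
over all mapped catheter positions of that cycle. Missing pairs are
dropped pairwise throughout.

## Benchmark metrics and selection

Accuracy = mean |T̄_MR − T̄_probe|, bias = signed mean difference
(negative ⇒ MR underestimates), precision = sample (n−1) SD of the ROI
mean across scan times — the deliberate reading of "variability of the
spatial mean temperature in an ROI across all time points" (the shorthand
std(1/n ΣT̄) would be the SD of a single number). A session is
*acceptable* when the mean of its per-location accuracies is ≤ 1 °C
(boundary inclusive). Locations are compared by classical one-way ANOVA;
groups with zero within-variance but unequal means are rejected as
degenerate rather than reported as p ≈ 0.

ROC curves use thresholds at midpoints between sorted distinct scores plus
±∞, inclusive comparison on the positive side. Feature orientations are
declared from the physical argument (higher Jaccard and larger air-to-ROI
distance favor acceptability; larger air and fat volumes disfavor it) and
are configurable. AUC is trapezoidal and equals the Mann–Whitney
concordance with ties counted ½ (asserted against exhaustive pair
enumeration and scikit-learn). The operating cut-off minimizes the
distance to (0, 1) over *data* thresholds only (ties → lower FPR, then
higher TPR); it is NaN when all scores are identical. The 95% CI is a
stratified bootstrap percentile interval and the p-value a two-sided label
permutation test of AUC = 0.5 — resampling methods chosen because no
specific analytic method was mandated.

### Aggregation of the published clinical summary

`reproduce_table2_arithmetic` aggregates per-location means: overall =
mean of the three location means, reported at one decimal; deviations are
overall − 1 °C (accuracy, precision) and |overall| − 0.5 °C (bias). The
published improvement figures mix two aggregation routes, so both are
computed: comparing rounded overall means reproduces the quoted 50%
accuracy improvement, while averaging per-location relative improvements
reproduces the quoted 26% (precision) and 80% (bias, on magnitudes). The
published selected-set bias deviation (−0.3 °C) is not derivable from the
published per-location means, which give −0.2 °C; the package reports the
computed value.

## Synthetic session generator

The generator emulates the clinical acquisition (25 axial slices, 256²
reconstruction over 50 × 50 cm, 1 cm slices, 83 s scans; two baselines
97 s apart; ~9 treatment scans; probe mapping every 300 s, 1 cm steps,
≤ 14 positions), scaled to 128²×15 (recovery experiments) or 64²×9
(cohort studies) for desk-scale runtime.

* **Anatomy**: elliptical body cross-section; subcutaneous fat ring
  (default 1.6 cm, randomized 1.2–2.2 cm across cohorts so fat volume is a
  decoupled nuisance feature); three probe tracks spanning 2–8 slices at
  jittered anchor positions; air pockets grown from seeds near the tracks
  to the requested volume (exact to the nearest voxel).
* **Controlled air motion**: the second-baseline mask B derives from A by
  removing k trailing-edge voxels and adding k fresh leading-edge voxels
  with k = |A|·f/(2 − f), so J(A, B) = 1 − f exactly up to integer
  rounding — the Jaccard coefficient is a controlled input, not an
  emergent property.
* **Heating**: Gaussian focus (default σ = 4 cm, peak 3–6 °C — the
  magnitude regime of reported pelvic treatments) with saturating
  exponential ramp (τ = 12 min) starting after the second baseline; fat is
  kept thermally inert so the drift reference is valid in the truth.
* **Confounders**: quadratic in-plane drift growing linearly in time to
  0.05 rad by session end; i.i.d. phase noise (default 3 × 10⁻³ rad,
  ≈ 0.55 °C per voxel pair-difference at the default α); a dipole-like
  susceptibility pattern (exp(−d/1.5 cm)·cos 2θ around the air pockets)
  whose amplitude scales with `air_artifact_rad` × (1 − J), i.e.
  monotonically with inter-baseline air displacement. Any monotone link
  suffices for the selection experiment; no claim of field-solver realism
  is made.
* **Probes** sample the continuous-time truth at the track voxels plus
  0.1 °C noise.

All randomness flows from one seed through `SeedSequence` spawning;
identical seeds give bit-identical sessions.

**What the generator does not emulate** — intra-scan motion blur,
respiration and bulk patient motion, bladder filling, actual susceptibility
field physics, coil/B1 inhomogeneity, k-space sampling, fat-water chemical
shift in magnitude images, probe self-heating. Passing tests therefore
demonstrate the correctness and internal consistency of the reconstruction
and selection machinery under the modeled confounders, not clinical-grade
performance on real data.

## Study sizes and numerical choices

Recovery experiments use 128²×15 with 11 scans; the drift-recovery
experiment uses drift 0.08 rad with phase noise 5 × 10⁻⁴ rad (≈ 44 dB),
so the measured RMSE reflects drift-fit fidelity rather than the noise
floor (at the default α, 10⁻³ rad of noise alone already costs ≈ 0.18 °C
RMSE via √2σ/|γαB₀TE|). Cohort experiments use 30 sessions at 64²×9 with
motion fractions graded linearly over [0, 0.75]. Threshold search grid:
0.1 °C; drift basis: {1, x, y, x², xy, y²} on [−1, 1]; ROC distance ties
broken toward specificity; all tolerances asserted in the test suite are
stated in the tests themselves.

Known limitations: the exclusion-threshold optimum is dynamic-range
dependent (see above); single-voxel ROIs at matrix 64 make per-slice ROI
means noisy; the min-distance feature uses a FOV-diagonal cap for air-free
slices, which compresses its dynamic range when air is sparse; the
generator's artifact is in-plane dipole-like only.
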