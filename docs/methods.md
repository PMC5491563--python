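# Methods

## Bolus model

The package models a pixel's contrast passage with the modified local
density random walk (LDRW) solution of the convective-diffusion equation,

C(t) = α √(κ / (2π(t − t₀))) · exp(−κ (t − t₀ − μ)² / (2(t − t₀)))  for t > t₀,

and C(t) = 0 otherwise. Using
∫₀^∞ s^(ν−1) e^(−as − b/s) ds = 2(b/a)^(ν/2) K_ν(2√(ab)) with
half-integer modified Bessel functions (a = κ/2, b = κμ²/2, 2√(ab) = λ = μκ):

* area: ∫ C dt = α exactly;
* first moment about t₀: μ(1 + 1/λ);
* central second moment: (μ/κ)(1 + 2/λ);
* mode: ((1/κ² + 4μ²)^½ − 1/κ)/2 ≈ μ − 1/(2κ).

These identities are verified against adaptive quadrature in the unit
tests. The conventional readings "μ is the mean transit time" and
"var = μ/κ" are therefore the λ → ∞ limits; at physiological λ ≈ 10–100
they deviate by 1/λ and 2/λ (1–10%). The fitted parameter reports follow
the field convention (var ≡ μ/κ, λ ≡ μκ, exact identities of the returned
fit), while the documentation and tests keep the exact moments explicit.

## Fitting

Bounded trust-region nonlinear least squares with an analytic Jacobian,
initialized deterministically from curve landmarks (t₀ from the 5%
appearance time, μ from the peak delay, κ by moment-matching the FWHM,
α from the trapezoidal area). One retry from a perturbed start; tolerances
1e-8; at most 200 function evaluations. The fitting window runs from the
first positive sample to the truncation time — the first prominent local
minimum after the peak of the lightly smoothed TIC (Gaussian, σ = 2 s,
prominence ≥ 5% of peak) — so the recirculation pass is excluded; `int` is
the peak-to-truncation interval. A fit with optimizer failure or R² below
the configurable floor (default 0.5) marks the pixel unfittable; such
pixels are excluded from classification but kept in the denominator of
all retained-fraction reports.

Identifiability note: with noisy data, errors in t₀ and μ are almost
perfectly anti-correlated (their sum, the arrival-to-peak landmark, is
well determined; the split is not). Temporal smoothing controls this by
raising the SNR of the curve foot; the residual μ scatter is the main
error source of the kinetic features.

## Preprocessing

Scanner loops are log-compressed; `linearize` inverts
g ↦ 10^(g·DR/(10·G_max)) with a configurable dynamic range (default 30 dB,
G_max = 255). The exact clinical mapping is proprietary, so this is a
documented stand-in, exact on round trips with its own `compress`.

Two separately preprocessed copies of each loop feed the analyses:

* fitting/perfusion chain — Gaussian spatial smoothing (default σ = 1.0 mm)
  plus a zero-phase second-order Butterworth low-pass (default 0.5 Hz);
  bolus dynamics on a two-minute scale live well below 0.5 Hz and the
  zero-phase filter preserves the timing landmarks (AT, PT);
* similarity chain — temporal filter only. Spatial smoothing before
  similarity analysis would mix neighboring TICs and erase precisely the
  neighborhood decorrelation that r and ρ measure.

Baseline: the bolus arrival is the first frame where the field-mean
intensity (above its minimum) exceeds 5% of its excursion — the same 5%
convention as the appearance time. The per-pixel median over the
pre-arrival frames is subtracted and the result clipped at zero; that
median also provides the greylevel (pre-contrast echogenicity) feature.

## Perfusion parameters

PI and PT are the maximum and the time of its first occurrence
(tie-break: earliest). AT, the 95% wash-in endpoint, and both FWHM
crossings are linearly interpolated between samples, making the timing
features frame-rate independent; all thresholds are relative to PI, so
timing features are invariant under intensity scaling. FWHM is flagged
undefined when a truncated recording never falls below half maximum after
the peak.

## Similarity analysis

The ring kernel contains every integer pixel offset whose Euclidean
distance lies in [1.0, 2.5] mm; the offset count depends on the pixel
spacing (20 at 1.0 mm spacing, the brute-force-enumerated reference set). The analysis window is [AT − 5 s, AT + 20 s] of
the field-mean TIC. r is the mean Pearson correlation between the
windowed center TIC and each neighbor TIC; ρ is the mean magnitude-squared
coherence (Welch estimate: Hann window, constant detrend, 50% overlap,
segment length auto-chosen ≈ one third of the window) averaged over the
0–0.5 Hz band, DC excluded. The per-pair estimator is numerically
identical to `scipy.signal.coherence` at equal settings (asserted in the
tests); the map computation vectorizes the same arithmetic over all
pixels and offsets. Border pixels use the neighbors that remain inside
the image; pixels with fewer than half the full ring (default) are
invalid. With few Welch segments the coherence estimator has a positive
null bias (≈ 1/n_segments); the independent-noise null is asserted below
0.3, not 0. Estimator settings are declared stand-ins: the clinically
used windowing is not recoverable, so similarity results are validated
property-wise (bounds, nulls, invariances, class ordering by
construction), not value-wise.

## Classification

Per class a Gaussian mixture over the selected features, normalized by
the training 90th percentile per feature (linear interpolation between
order statistics; scales always come from the training prostates and are
reused on the held-out prostate). Default one component per class — the
empirically adequate choice, reducing EM to the exact mean/covariance
estimate and making the classifier equal to a closed-form two-Gaussian
quadratic discriminant (asserted to 1e-9 against an independent oracle).
More components run full EM (scikit-learn, ridge 1e-6 on covariance
diagonals, tol 1e-8, max 500 iterations, fixed seed). Class priors are
equal by default, configurable to empirical. Confidence
P = 2p_A/(p_A + p_B) − 1; ties classify as benign with P = 0. "Absolute
probability" for exclusion is the winning class-conditional density
(not the posterior), configurable.

Leave-one-prostate-out: all pixels of one prostate are held out per fold;
metrics are unweighted means ± sd across prostates; undefined metrics
(zero denominators) propagate as missing and are skipped in averages,
never counted as zero. The subset search evaluates every feature subset
of size 1–4 (1470 subsets for the 14-feature panel) and ranks by mean
accuracy and separately by NPV, ties toward fewer parameters then
lexicographic names.

Exclusion sweeps retain pixels with measure ≥ threshold (confidence, R²,
absolute probability) or drop the lowest-PT fraction per plane
(early-arriving large vessels); unfittable pixels are excluded at every
threshold and retained fractions are reported against all ROI pixels,
overall and per class.

## Synthetic phantom

The generator emulates two-minute transrectal contrast loops: per-pixel
LDRW TICs on a static echogenicity pedestal, a delayed recirculation pass
(second LDRW with the same μ, κ, delay 45 s, amplitude fraction 0.25),
multiplicative Gaussian noise (intensity-proportional, a first-order
stand-in for log-compressed speckle) plus a small additive floor, applied
after temporal synthesis and clipped at zero. Lesions are rasterized
random ellipses (axis ratio 1–2) of 0.5 cm² — the scale of clinically
relevant foci — placed without overlap, with equal-sized benign reference
ROIs away from lesion rims. Parameter fields are white Gaussian fields
smoothed to a class-specific correlation length and affinely mapped to
the class distribution, so similarity features carry class signal by
construction.

Defaults (chosen once as a physiologically plausible regime; the paper
trail for this kind of study reports directions — rapid, enhanced, more
dispersed inflow in malignant tissue — not quantitative contrasts, so
these must not be read as estimates of clinical values):

| parameter | benign | malignant |
|---|---|---|
| α (a.u.·s) | 15 ± 2.5 | 20 ± 4 |
| μ (s) | 25 ± 3 | 19 ± 3 |
| κ (s⁻¹) | 0.60 ± 0.12 | 0.90 ± 0.18 |
| t₀ (s) | 8.0 ± 0.8 | 6.8 ± 0.8 |
| echogenicity (a.u.) | 0.30 ± 0.05 | 0.22 ± 0.05 |
| coherence scale (mm) | 1.3 | 1.1 |

Grid 64×64 at 0.5 mm/pixel, 10 Hz default frame rate, 120 s duration;
noise 10% multiplicative + 0.02 additive. Within a class, κ is partially
anti-correlated with μ (coupling 0.8): λ = μκ varies less across tissue
than either parameter, which reproduces the strong clinical coupling of
wash-in time with μ. Cohorts add prostate-level effects drawn once per
prostate — shifts of μ and t₀, log-normal gains on α, on the coherence
scales and on the noise level — modelling circulation, dose, texture and
recording-quality differences between patients; every loop has its own
RNG stream derived from (seed, prostate, plane), so cohorts are
reproducible plane by plane.

What the phantom does not emulate: acoustic propagation, beamforming,
true speckle statistics (fully developed speckle is neither Gaussian nor
pixelwise independent), motion, attenuation, 3-D geometry, microbubble
disruption. Passing tests therefore demonstrate that the analysis chain
recovers planted structure of this kind under realistic noise — not
clinical performance.

## Study scales

Scales used by the acceptance checks and analysis scripts, chosen as
desk-scale versions of the study design: noiseless round trips on the
full 64×64 default phantom at 10 Hz; cohort studies on 64×64 planes at
4 Hz (the temporal grid is oversampled for sub-0.5 Hz bolus dynamics even
at 4 Hz), 4–8 prostates with 1–2 planes each, LDRW fits restricted to ROI
pixels with at most 60–80 pixels per ROI (deterministic subsample), and
20 independently seeded cohorts for the mechanism study.

## Known limitations

* The t₀–μ trade-off inflates μ scatter at low SNR; a joint spatial prior
  on t₀ would help and is not implemented.
* Exclusion thresholds on confidence are cohort-dependent; the quantile
  grid used in the sweeps reports accuracy against retained fraction
  rather than against an absolute P scale.
* The log-compression mapping, the similarity estimator settings and the
  noise model are declared stand-ins for unrecoverable clinical
  processing details; all are configurable.
* With a single mixture component the classifier is exactly a quadratic
  discriminant; multimodal class distributions need n_components > 1,
  which is implemented but not the tested default.
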