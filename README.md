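# mpdceus — multiparametric DCE-US analysis

Localizing prostate cancer with dynamic contrast-enhanced ultrasound
(DCE-US) means watching an intravenous microbubble bolus wash through the
prostate and asking, pixel by pixel, whether the local hemodynamics look
malignant. No single time-intensity-curve (TIC) parameter separates the
classes well; this package implements the multiparametric route: extract
perfusion, bolus-kinetics and dispersion-similarity parameters per pixel,
fuse a small subset of them with a two-class Gaussian-mixture classifier,
validate with leave-one-prostate-out cross-validation, and suppress
unreliable pixels by classification confidence. Because no patient
recordings are distributable, a synthetic phantom generator with known
ground truth stands in for the clinical loops and makes every stage
testable end to end.

## The model

Each pixel's baseline-subtracted TIC is fitted by the modified local
density random walk (LDRW) indicator-dilution model

$$C(t) = \alpha\,\sqrt{\frac{\kappa}{2\pi\,(t-t_0)}}\;
\exp\!\left(-\frac{\kappa\,(t-t_0-\mu)^2}{2\,(t-t_0)}\right),\qquad t>t_0,$$

with area under the curve α (a.u.·s), transit-time parameter μ (s),
skewness κ (s⁻¹), arrival offset t₀ (s), and derived parameters
λ = μκ (convective-to-diffusive time ratio) and var = μ/κ. The curve
integrates exactly to α; its first moment about t₀ is μ(1 + 1/λ) and its
central variance (μ/κ)(1 + 2/λ), so μ and μ/κ are the mean transit time
and variance in the physiological large-λ regime.

The full per-pixel panel has 14 parameters:

* B-mode: greylevel (pre-contrast echo intensity);
* perfusion: WIT, AT, PT, PI, FWHM (threshold crossings of the TIC,
  linearly interpolated);
* curve fitting: κ, μ, λ, α, var, int (the fitting interval between the
  peak and the recirculation truncation);
* similarity: spatiotemporal correlation r and spectral coherence ρ of a
  pixel's TIC against its neighbors in a ring kernel of 1.0–2.5 mm radius
  — bolus dispersion through angiogenic microvasculature lowers local TIC
  similarity.

Classification describes each class (benign / malignant) by a Gaussian
mixture (one component per class by default) over 90th-percentile
normalized features; the classification confidence is
P = 2p_A/(p_A + p_B) − 1 with A the more probable class. Performance is
reported as accuracy, sensitivity, specificity, PPV and NPV averaged over
held-out prostates.

## Worked example

```python
from mpdceus import (PhantomConfig, generate_cohort, cohort_dataset,
                     FeatureConfig, evaluate_loo)

cfg = PhantomConfig(frame_rate=4.0, seed=7)          # 64x64, 120 s loops
planes = generate_cohort(cfg, n_prostates=8, planes_per_prostate=1, seed=7)
ds = cohort_dataset(planes, FeatureConfig(max_pixels_per_roi=80))
res = evaluate_loo(ds, ("r", "mu", "kappa", "PT"))
print({k: round(v, 1) for k, v in res.mean.items()})
```

prints

```
{'accuracy': 88.9, 'sensitivity': 85.8, 'specificity': 92.0, 'ppv': 92.3, 'npv': 87.5}
```

i.e. on this synthetic 8-prostate cohort the fused set {r, μ, κ, PT}
classifies 88.9% of held-out ROI pixels correctly (mean over prostates),
versus 85.6% for the best single parameter (r) — fusion of a dispersion
feature with kinetic features beats every individual parameter. Excluding
the lowest-confidence half of the pixels raises accuracy to 98.4% on the
same cohort (`analysis/05_pixel_exclusion.py`).

The numbered scripts under `analysis/` run the same stages as a narrative
sequence (simulate → extract → classify → search → exclude → multi-seed
study) and write their tables to `results/`.

## Layout

```
src/mpdceus/        library: synthetic, preprocessing, perfusion, ldrw,
                    similarity, features, dataset, classification,
                    evaluation, studies, pipeline, io, cli
analysis/           numbered narrative drivers
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     model, assumptions, parameter choices, limitations
```

A thin command-line interface is installed as `mpdceus`
(`simulate / preprocess / fit / similarity / classify / search / exclude /
run`); `mpdceus run --config run.yaml` executes the whole pipeline from a
single YAML configuration and writes a manifest sufficient to reproduce
the run.
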