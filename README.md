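# tendonqus

Quantitative ultrasound (QUS) analysis of tendon integrity: extract eleven
measurements from grayscale B-mode images within traced regions of interest,
then quantify their test–retest reliability with generalizability theory
across simulated measurement protocols.

## What it does

* **`tendonqus.roi_io`** — reads 8-bit PNG/JPEG frames, attaches a pixel
  calibration (default pixel area 0.0057 mm²), parses ROI tracings from JSON
  (a contour polygon for transverse views, paired edge polylines for
  longitudinal views) and rasterizes them with a pixel-center-in-region rule.
* **`tendonqus.features`** — the measurement set: geometric (mean thickness
  from 100 paired edge points; bounding-rectangle thickness/width and
  shoelace area for transverse contours), first-order grayscale statistics
  (echogenicity, variance, skewness, kurtosis, histogram entropy; population
  denominators, non-excess kurtosis) and gray-level co-occurrence texture
  (contrast, energy, homogeneity at distance 10 px, averaged over the
  0°/45°/90°/135° directions, 256 levels, symmetric counting).
* **`tendonqus.gtheory`** — G-study variance components of the fully crossed
  Subject × Evaluator × Visit × Image random design (EMS method of moments,
  15 effects) and D-study projections: dependability Φ, SEM, and minimal
  detectable change `MDC_abs = 1.65·√2·SEM` with its percent-of-mean form.
* **`tendonqus.synthetic`** — speckle phantoms with ground-truth geometry
  (healthy: bright, striated, thinner; pathologic: thicker, darker, with a
  hypoechoic blob) and balanced crossed study tables generated either from a
  linear random model with known variance components or by rendering and
  measuring an image per design cell.
* **`tendonqus.pipeline`** — the `qus` command line: `simulate`, `extract`,
  `summary` (group means/SD/95% CI and between-group percent differences)
  and `reliability` (variance-proportion table plus the D-study grid for one
  evaluator, 1–2 visits, 1–3 images).

## Command-line walkthrough

```sh
qus simulate --out-dir study --n-subjects 6 --roi-jitter 2.5 --seed 1
qus extract study/design.csv --out study/features.csv
qus summary study/features.csv --out study/summary.csv
qus reliability study/features.csv --out-dir study/reliability
```

`reliability` writes `variance_proportions.csv` (each row sums to 100%),
`dstudy_grid.csv` (Φ, SEM, MDC90%_norm and an interpretation label per
protocol) and a combined `report.json`.

## Python API sketch

```python
import tendonqus as tq

image, roi, truth = tq.simulate_tendon_image(tq.healthy_params(seed=0))
features = tq.extract_features(image, roi)          # thickness, echogenicity, ...

table = tq.simulate_feature_study(
    tq.StudySimParams(n_s=50, variance_components={"S": 1.0, "SEVI": 0.2}, seed=0)
)
vc = tq.estimate_variance_components(table)
result = tq.dstudy(vc, n_e=1, n_v=1, n_i=3, group_mean=table["value"].mean())
print(result.phi, result.sem, result.mdc_norm, result.interpretation)
```
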