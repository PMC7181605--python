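# fibroquant

Morphometric quantification of renal interstitial fibrosis (mIF) from
bright-field Sirius-Red-stained sections, with per-slide internal stain
calibration, a synthetic-histology generator for ground-truth testing, and
the reproducibility statistics used to validate this kind of readout.

## The problem

Interstitial fibrosis — replacement of functional cortical tissue by
fibrillar collagen — is the hallmark chronic lesion of kidney allografts,
and early fibrosis predicts long-term graft dysfunction. The standard
visual readout, the Banff `ci` grade, is semi-quantitative (four grades,
0–3) and shows wide inter-observer variation, so slight but real
progression between biopsies is easily missed. A continuous morphometric
readout addresses both limitations: digitize a Sirius-Red-stained section,
outline the cortex, delete glomeruli and medium arteries, classify every
remaining pixel as collagen-positive or not, and report

```
mIF = 100 × (Sirius-Red-positive pixels) / (evaluated cortical pixels)   [%]
```

Because sections are stained in different batches whose intensity and hue
drift, pixel classification is calibrated **per slide** from
operator-selected internal reference patches: a positive patch (pure red
collagen) and a negative patch (counterstained tissue) on that same slide.
fibroquant models each class as a Gaussian in a cyclic-hue HSV-derived
color space, `(cos 2πh·s, sin 2πh·s, v)`, and labels a pixel positive when
the log-likelihood ratio favors the positive class. A staining-batch shift
moves both reference classes and the decision boundary with them, which is
what makes slides from different batches comparable.

The package is aimed at renal pathologists and image-analysis researchers
who want a transparent, scriptable alternative to proprietary morphometry
software, plus the statistics to validate it: one-way random-effects
ICC(1,1) with F-based confidence intervals for inter-/intra-observer
agreement, Fisher-z intervals for Pearson correlations, paired location
tests and simple OLS for longitudinal and clinical associations.

## Worked example

No real slides ship with the package; the synthetic generator renders a
cortex with tubules, glomeruli and interstitial collagen at a known
fraction, plus the annotations an operator would draw:

```python
import fibroquant as fb

slide = fb.generate_slide(
    fb.SynthConfig(fibrosis_fraction=0.18, batch_gain=0.9, seed=23)
)
calib = fb.calibration_from_annotations(slide.image, slide.annotations)
result = fb.compute_mif(slide.image, slide.annotations, calib)
print(f"true fraction : {100 * slide.realized_fraction:.2f}%")
print(f"mIF           : {result.mif_percent:.2f}%")

lo, hi = fb.icc_ci_from_estimate(0.75, n=151, k=2)
print(f"ICC 0.75 (n=151, k=2) 95% CI: [{lo:.2f}, {hi:.2f}]")
```

prints

```
true fraction : 18.00%
mIF           : 18.00%
ICC 0.75 (n=151, k=2) 95% CI: [0.67, 0.81]
```

The slide was rendered at 18% collagen with a 0.9 staining gain; the
pipeline recovers 18.00% because the calibration patches see the same
batch transform as the tissue. The last line reconstructs the 95%
confidence interval that an ICC(1,1) point estimate of 0.75 implies at
n=151 subjects and k=2 raters — the F-pivot inversion used to check
published agreement studies without raw data.

The same operations are available from a shell:

```bash
fibroquant simulate-slide --seed 23 --out-dir slide23/
fibroquant quantify --image slide23/image.png \
    --annotations slide23/annotations.geojson --out result.json
fibroquant stats icc-ci --icc 0.75 --n 151 --k 2
fibroquant simulate-cohort --n 66 --seed 1 --out-dir cohort/
fibroquant cohort-report --patients cohort/patients.csv \
    --biopsies cohort/biopsies.csv --out report.json
```

Real slides enter the same way: an 8-bit RGB PNG/TIFF per section and a
GeoJSON FeatureCollection of polygons with roles `cortex`, `exclusion`,
`ref_positive`, `ref_negative`.

## Layout

| Module | Contents |
| --- | --- |
| `fibroquant.image_io` | PNG/TIFF + GeoJSON I/O, polygon rasterization (pixel-center convention) |
| `fibroquant.fibrosis_quant` | stain calibration, pixel classification, mIF, batch runs |
| `fibroquant.synth_histology` | synthetic slides with exact ground truth |
| `fibroquant.biostats` | ICC(1,1), Fisher-z CIs, paired tests, OLS, simulators |
| `fibroquant.cohort` | longitudinal cohort synthesis, progression & association analyses |
| `fibroquant.cli` | `fibroquant` command-line entry point |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
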