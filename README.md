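# carfind

Label-free counting of CAR T-cells captured from whole blood on a
CD19-functionalized microfluidic sensor, from brightfield microscopy
alone. `carfind` is the image-analysis half of such an assay: it finds
cell-like objects in 16-bit brightfield tiles, classifies them, turns
per-channel counts into concentrations through a calibration curve with
detection/quantification limits, and validates capture specificity with
paired fluorescence images. It is written for assay developers and
analysts who have the images and need numbers.

## What it computes

**Detection** is a five-stage prefilter: a local standard-deviation
filter (rectifies contrast polarity and suppresses flat background), a
matched filter — zero-mean normalized cross-correlation with a
cell-sized disc template — negative-value thresholding, local-maxima
identification with minimum peak separation, and radial ray-cast
segmentation of each peak into a footprint. Candidates are then sorted
into four classes (CAR T-cell, platelet, residual RBC, other/debris) by
a 100-tree random forest over 16 shape/intensity/texture features,
reported one-vs-rest as sensitivity TP/(TP+FN) and specificity
TN/(TN+FP) for the CAR T class.

**Quantification** fits counted cells y against spiked concentration x
(cells/µL) with either a power law y = a·x^b (buffer, fitted log-log)
or y = a·ln x + b (whole blood, which carries a >100-count white-cell
background). Limits of detection and quantification at 95% certainty
come from blank statistics pushed through the fitted curve:

    y_D = blank_mean + 2·1.645·blank_sd   →  LOD = curve⁻¹(y_D)
    y_Q = blank_mean + 10·blank_sd        →  LOQ = curve⁻¹(y_Q)

**Fluorescence validation** pairs each brightfield detection with a disc
ROI on the fluorescence image and computes SD/median of the ROI pixels
— a gain-invariant per-cell statistic that is high for clustered CAR
staining. A two-Gaussian mixture (EM) splits expressers from
non-expressers at the intersection of the weighted component densities,
giving the positivity fraction.

A bundled synthetic-data generator renders ground-truthed brightfield
and fluorescence tiles (ring-contrast lymphocytes of 7–15 µm, platelets,
RBCs, debris, at 0.1625 µm/px) plus Poisson calibration count tables,
so the entire chain is testable end to end without instrument data.

## Worked example

```python
from carfind import (
    CalSimConfig, SceneConfig, count_sample, evaluate, fit_power,
    lod_loq, make_object_library, render_tile, simulate_calibration,
    train_classifier,
)

# 1. Train the classifier on the synthetic library (150/category, 100/50 split)
train, test = make_object_library(n_per_class=150, split=(100, 50), seed=0)
model = train_classifier([(c.features, cls) for c, cls in train], seed=0)
report = evaluate(model, [(c.features, cls) for c, cls in test], positive="CART")
print(f"CART sensitivity: {report.sensitivity['CART']:.2f}")
print(f"CART specificity: {report.specificity['CART']:.2f}")

# 2. Count a 30-tile channel scan spiked with 2 cells per tile
scene = SceneConfig(densities={"CART": 2, "PLATELET": 0, "RBC": 0, "OTHER": 0},
                    crowding=95, exact_counts=True)
tiles = [render_tile(scene, seed=100 + i)[0] for i in range(30)]
result = count_sample(tiles, model)
print(f"CART count over 30 tiles: {result.cart_count}")

# 3. Calibrate on a simulated buffer dilution series and invert
table = simulate_calibration(CalSimConfig(seed=0))
spiked = table[table.concentration > 0]
blanks = table[table.concentration == 0]
fit = fit_power(spiked.concentration, spiked.observed_count)
lod, loq = lod_loq(fit, blanks.observed_count.mean(), blanks.observed_count.std(ddof=1))
print(f"power fit: a={fit.a:.2f}, b={fit.b:.3f}, R^2={fit.r_squared:.3f}")
print(f"LOD={lod:.2f} cells/uL, LOQ={loq:.2f} cells/uL")
print(f"estimated concentration: {fit.invert(result.cart_count):.1f} cells/uL")
```

prints

```
CART sensitivity: 1.00
CART specificity: 1.00
CART count over 30 tiles: 60
power fit: a=5.09, b=1.033, R^2=0.995
LOD=0.14 cells/uL, LOQ=0.42 cells/uL
estimated concentration: 10.9 cells/uL
```

The classifier is perfect here because synthetic classes are cleaner
than real blood objects; the count recovers all 60 spiked cells; the
dilution series (1–1000 cells/µL in triplicate, 0.85 capture efficiency
into a 7.1 µL channel) fits a near-unit-exponent power law, and the
count converts to concentration by inverting that curve.

The same workflow is available from the shell:

```bash
carfind config    --out cfg.json
carfind simulate  tiles --out tiles/ --seed 1
carfind detect    --image tiles/tile_000.tif --out det.csv --save-stages stages/
carfind train     --objects objects.csv --out model.bin --seed 1
carfind count     --tiles tiles/ --model model.bin --out counts.json
carfind calibrate --counts counts.csv --form power --blanks blanks.csv --out fit.json
carfind run       --tiles tiles/ --model model.bin --fit fit.json --out report/
carfind fluor     --rois det.csv --fluor f.tif --out stats.csv
carfind gate      --stats stats.csv --out mixture.json
```

`carfind run` writes a JSON + human-readable report with per-class
counts, the estimated concentration, and a flag (`not detected` /
`detected, below quantification` / `quantified`) tied to the stored
LOD/LOQ, plus a manifest with config snapshot, input hashes and seeds.

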