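# vigormap

Semi-automated mapping of wildlife crop damage (typically wild-boar rooting
in maize) from UAV RGB orthomosaics. The package turns a plain 3-band
GeoTIFF plus a field-boundary polygon into vigor classification maps, binary
damage masks, per-class area statistics and HTML/Markdown reports — no
multispectral sensor, training data or GIS expertise required. It is aimed
at drone data analysts, field technicians and researchers who need fast,
repeatable damage inventories for compensation and precision-agriculture
decisions.

## Method

1. **Clip** the orthomosaic to the cultivated area (pixel-center-in-polygon
   rule; pixels outside become nodata, the georeference is untouched).
2. **Normalize** the RGB channels to [0, 1] by bit-depth division and
   compute three vegetation indices per pixel:

   * ExG = 2g − r − b (Excess Green)
   * GLI = (2g − r − b) / (2g + r + b) (Green Leaf Index)
   * MGRVI = (g² − r²) / (g² + r²) (Modified Green-Red Vegetation Index)

   plus a **composite**: the mean of the three indices after each is
   min–max rescaled to [0, 1] over the field.
3. **Vigor zoning**: k-means (k = 5) on the standardized (ExG, GLI, MGRVI)
   features partitions the field into five classes, relabeled by descending
   mean composite: 0 Very Good … 4 Very Poor.
4. **Damage detection**: within each vigor class, the weakest 25% of pixels
   by composite (per-class fractions are tunable in [0, 1]) are flagged;
   the five masks union into the final binary damage raster. Selection is
   rank-based — exactly ⌊f·n⌋ pixels per class — so counts are deterministic.
5. **Area statistics**: damage area (ha) and share (%) per class and in
   total, shares computed against the whole field area.
6. **Accuracy assessment**: reference points placed by seeded rejection
   sampling with a minimum pairwise spacing (default 100 points, 15 m),
   compared against the class raster: confusion matrix, per-class
   precision/recall/F1/support, overall accuracy, macro/weighted averages.

A seeded synthetic-field generator (five spatially coherent vigor strata,
circular planted damage patches, known ground truth) makes the whole
pipeline testable end to end without flying a drone.

## Worked example

```python
from vigormap import (SyntheticFieldSpec, generate_field, clip_to_boundary,
                      compute_index_stack, classify_vigor, detect_damage,
                      summarize, format_summary_table, pixel_area_m2)

field = generate_field(SyntheticFieldSpec(seed=7))     # 512×512 px, 6.5 cm GSD
clipped = clip_to_boundary(field.ortho, field.boundary)
stack = compute_index_stack(clipped)
vigor = classify_vigor(stack, k=5, seed=42)
masks = detect_damage(stack.composite, vigor)          # default: weakest 25%
summary = summarize(vigor, masks, pixel_area_m2(clipped), field.boundary.area_m2)
for name, ha, pct in format_summary_table(summary):
    print(f"{name:<10} {ha:>6} ha  {pct:>5} %")
recall = masks.aggregated[field.damage_mask].mean()
print(f"planted-damage recall: {recall:.3f}")
```

prints

```
Very Good    0.01 ha    5.0 %
Good         0.01 ha    5.0 %
Moderate     0.01 ha    5.0 %
Poor         0.01 ha    5.0 %
Very Poor    0.01 ha    5.0 %
Total        0.03 ha   25.0 %
planted-damage recall: 0.984
```

The desk-scale demo field is ~0.10 ha, each class flags exactly 25% of its
pixels (hence the uniform 5.0% shares summing to 25.0% of the field), and
the default masks recover 98.4% of the planted damage pixels.

## Command line

```sh
vigormap simulate --out field --seed 0          # synthetic orthomosaic + boundary + labels
vigormap init --config run.toml                 # write a run configuration
vigormap run --config run.toml --workdir out    # clip → indices → cluster → detect → report
vigormap detect --config run.toml --fraction-class 3=0.30   # retune one class
vigormap validate --config run.toml --reference field/reference_labels.csv
```

Each run directory receives the clipped raster, four index rasters, the
vigor-class map, per-class and aggregated damage masks
(`damage_class0..4.tif`, `damage_all.tif`), `area_summary.csv`, a manifest
with checksums, and `report.html` / `report.md`.

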