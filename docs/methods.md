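# Methods

## Model and assumptions

The pipeline treats wildlife damage as a *within-class radiometric outlier*
problem. Crop canopies vary smoothly in vigor across a field, so a global
index threshold confuses "weak but intact" zones with true disturbance.
Instead the field is first partitioned into five vigor classes by
unsupervised clustering of RGB vegetation indices, and damage is then
defined *relative to each class*: the fraction of pixels with the lowest
composite index inside each class. The approach assumes (a) damage lowers
greenness relative to the pixel's local vigor context, (b) five classes
suffice to absorb field-scale vigor gradients, and (c) the orthomosaic is
radiometrically consistent across the scene (single flight, uniform
illumination). No temporal, structural or multispectral information is used.

## Index computation

Channels are normalized by bit-depth division (DN / (2^depth − 1)); for
float rasters an explicit scale must be given, since a per-scene min–max
stretch would couple the indices to scene content. ExG is computed on the
normalized channels directly; a chromatic-coordinate variant
(`exg_chromatic`) is available because both forms circulate in the
literature. Pixels with a zero index denominator (pure black, e.g. deep
shadow or border artefacts) are marked invalid and excluded from clustering
and thresholding rather than zero-filled — zero-filling would plant fake
"damage" at shadows.

The composite used for ranking is the mean of the three indices after each
is min–max rescaled to [0, 1] over valid field pixels. Raw averaging would
weight ExG (native range 4) double relative to GLI/MGRVI (range 2);
rescaling makes the mean scale-balanced. A raw-mean variant
(`rescale=False`, which rescales the mean itself so the composite stays in
[0, 1]) is provided for comparison. A constant index contributes 0.5
everywhere by convention, so it neither promotes nor demotes any pixel.

## Vigor zoning

k-means with k = 5, k-means++ initialization, 10 restarts, 300 max
iterations, tolerance 1e-4 and a fixed default seed (42) — all
configuration-overridable — runs on z-standardized (ExG, GLI, MGRVI)
features. Standardization keeps ExG's wider spread from dominating the
Euclidean objective. Clusters carry no semantics by themselves; they are
relabeled 0..4 by strictly descending mean composite (ties broken by
ascending raw cluster id), which pins "Very Good" … "Very Poor" to stable,
reproducible labels. For very large rasters a seeded uniform subsample can
be clustered with nearest-centroid assignment of the remainder
(`cluster.sample`); the default clusters all valid pixels.

## Damage thresholding

Per class, exactly ⌊f·n⌋ pixels are flagged — the lowest-composite ones,
ties broken by row-major pixel order. Rank selection (rather than value
thresholding at an interpolated quantile) gives deterministic counts, is
well-defined under ties, and is equivalent for continuous data. Flooring
reads "the weakest 25%" as an at-most-f fraction. The default fraction is
0.25 for every class; per-class overrides live in `ThresholdConfig` and the
`detect --fraction-class` flag, and `retune` is a pure function so the
interactive field workflow (adjust → re-run → compare) is reproducible.
Rank selections are nested: raising a class's fraction can only grow its
mask, which makes iterative tuning monotone and predictable. No
morphological cleanup or minimum-mapping-unit filtering is applied.

## Areas and rounding

Areas are pixel counts × pixel area; shares are taken against the total
field area so per-class shares sum to the total share. Display rounding is
2 decimals (ha) and 1 decimal (%), using decimal half-up rounding, and is
applied only at output time — machine-readable exports always carry the raw
values. One consequence: a damage area of 1.35 ha on a 47.13 ha field
prints as 2.9% (100 × 1.35/47.13 = 2.864), even though one published
rendering of the same arithmetic prints 2.8.

## Accuracy assessment

Validation points are placed by seeded rejection sampling: uniform
candidates over the polygon's bounding box, accepted iff inside the polygon
and ≥ the minimum spacing (default 15 m) from all previously accepted
points. A plain rejection sampler was chosen over grid-accelerated
Poisson-disk dart throwing for clarity; `max_attempts` (default 10 000 × n)
bounds the search and the failure message names the achievable count.
Label extraction takes the pixel containing each point, resolving points on
exact pixel edges to the upper-left pixel; points on nodata are excluded
with a warning. Metrics are the standard confusion-matrix family; precision
or recall of a class absent from the sample is reported as 0 and flagged,
and macro averages include those zeros. `complete_confusion` reconstructs a
feasible confusion matrix from published supports/recalls/precisions
(diagonal plus marginals) via a transportation fill; all derived metrics
depend only on the diagonal and marginals, so the fill's arbitrariness is
immaterial.

## Synthetic fields

The generator emulates the study conditions at desk scale: a georeferenced
8-bit RGB grid (default 512×512 px at the survey's 6.5 cm ground sampling
distance, EPSG:2180) over a rectangular boundary inset from the raster
edge, five spatially coherent vigor strata (wavy horizontal bands,
quantile-cut to equal sizes) and circular damage patches (default radius
15 px) placed uniformly among still-undamaged field pixels until a target
share of the field is covered.

Radiometry is designed around two separability requirements rather than
photorealism:

* adjacent strata are ≈ 8–10 noise standard deviations apart in index
  space (stratum RGB triples grade from vivid green (60, 190, 50) to
  yellowed (150, 100, 70); channel noise sd 2.5 DN), so k-means recovers
  the strata essentially perfectly;
* the damage perturbation (+7, −7, +1) DN is ≈ 3 noise sd below its
  stratum's composite mean — below the stratum's 25th percentile — yet only
  ≈ 0.3× the adjacent-stratum gap, so damaged pixels stay in their own
  stratum's cluster and land in its weakest quartile.

The default damage fraction is 0.20 of the field: heavy but realistic boar
pressure, and large enough that the fixed 25% per-class selection is mostly
true damage (with damage ≈ 20% of each class and near-perfect separability,
expected recall ≈ 0.95+ and false-flag share ≈ 25%).

What the generator does **not** emulate: soil/row texture, view-angle and
illumination gradients, index saturation in dense canopy, mixed pixels at
damage edges, and georeferencing error. Passing recovery tests therefore
demonstrates the pipeline's correctness and determinism, not its field
accuracy on real imagery — on real orthomosaics class overlap is larger and
the default thresholds are meant to be tuned interactively.

## Numerical and I/O choices

* GeoTIFF georeferencing is read/written directly as the four standard tags
  (pixel scale, tiepoint, GeoKey directory, GDAL nodata) over tifffile;
  only metre-based projected CRSs are accepted, and a geographic or unknown
  CRS is rejected outright since every downstream quantity is metric.
  Boundaries are GeoJSON (polygon or multipolygon, unioned and repaired via
  buffer(0)).
* Pixel-in-polygon uses the pixel-center rule (no "all touched" inflation),
  making clipped areas exact on boundary-aligned rectangles and clipping
  idempotent.
* A pixel is nodata when all three bands equal the declared nodata value;
  the generator keeps in-field DNs ≥ 1 so 0 can serve as nodata.
* All randomness (k-means init, subsampling, point sampling, synthetic
  noise and patch placement) flows through explicit integer seeds;
  re-running any deterministic stage reproduces outputs checksum-for-
  checksum, which the run manifest records and tests assert.

## Problem sizes

The default test field is 512×512 px (~0.10 ha at 6.5 cm GSD; ~246 k valid
pixels), which exercises every stage in seconds while keeping the class
geometry non-trivial. The fixture generator's CLI default is 3340×3340 px
(~4.7 ha), the smallest scale at which 100 validation points with 15 m
spacing fit comfortably; `--full-scale` (10 560×10 560 px, ~47 ha)
reproduces the full survey extent when resources allow.

## Known limitations

* Damage is defined purely radiometrically; lodging that stays green, or
  senescent-but-intact zones, will be mis-ranked.
* The five-class contract is fixed by default; fields with fewer distinct
  vigor regimes still get five clusters, splitting homogeneous zones.
* The fixed per-class fraction flags ⌊0.25·n⌋ pixels whether or not any
  damage exists; interpretation (and retuning) remains the analyst's job.
* No reprojection: raster and boundary must share one projected CRS.
* Shapefile input is not supported; convert boundaries to GeoJSON.
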