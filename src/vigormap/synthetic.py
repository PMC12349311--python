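"""Seeded synthetic maize-field orthomosaics with known ground truth.

The study-scale input — a ~47 ha UAV RGB orthomosaic of a maize field with
wild-boar rooting damage — is emulated by a georeferenced 8-bit grid built
from five spatially coherent vigor strata (smooth wavy bands, mimicking the
spatially coherent vigor zoning of real canopies) with Gaussian pixel noise,
plus circular low-vigor damage patches planted at known locations.

Default radiometry is chosen for separability, which real orthomosaics only
approximate: adjacent strata differ by ≈ 8–10 noise standard deviations in
index space, and the damage perturbation is ≈ 3 noise sd below its stratum
mean (below the stratum's 25th composite percentile) yet only ≈ 0.3× the
adjacent-stratum gap (so damaged pixels still cluster with their own
stratum).  Ground truth (stratum raster + damage mask) is returned alongside
the imagery so every pipeline stage can be scored exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .raster import (CRS, FieldBoundary, GridTransform, RGBOrthomosaic,
                     write_boundary, write_orthomosaic)

#: per-stratum mean digital numbers (R, G, B), best → worst vigor:
#: vivid green canopy grading to yellowed, thinning cover.
DEFAULT_STRATUM_RGB = (
    (60, 190, 50),
    (85, 170, 55),
    (110, 150, 60),
    (135, 125, 65),
    (150, 100, 70),
)


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Generator parameters; defaults emulate the study conditions at desk scale."""

    width_px: int = 512
    height_px: int = 512
    pixel_size_m: float = 0.065          # the survey's 6.5 cm ground sampling distance
    n_strata: int = 5
    stratum_rgb: tuple = DEFAULT_STRATUM_RGB
    damage_fraction: float = 0.20        # share of in-field pixels rooted up
    damage_patch_radius_px: int = 15
    damage_rgb_delta: tuple = (7, -7, 1)  # rooting: browner, less green
    noise_sd: float = 2.5                # DN, per channel
    seed: int = 0
    boundary_inset_px: int = 8
    bit_depth: int = 8
    epsg: int = 2180
    origin: tuple = (500_000.0, 600_000.0)
    band_wave_amplitude_px: float | None = None  # default: height/8

    def __post_init__(self):
        greens = self.green_levels
        if any(later >= earlier for earlier, later in zip(greens[:-1], greens[1:])):
            # levels are best-first, so each must be below the previous
            raise ValueError("stratum green levels must be strictly descending")
        if not 0.0 <= self.damage_fraction <= 1.0:
            raise ValueError("damage_fraction must lie in [0, 1]")
        if len(self.stratum_rgb) != self.n_strata:
            raise ValueError("need one RGB triple per stratum")

    @property
    def green_levels(self) -> tuple:
        return tuple(rgb[1] for rgb in self.stratum_rgb)


@dataclass
class SyntheticField:
    ortho: RGBOrthomosaic
    boundary: FieldBoundary
    strata: np.ndarray          # int16 grid, −1 outside the field
    damage_mask: np.ndarray     # bool grid, planted damage pixels
    spec: SyntheticFieldSpec


def _stratum_layout(spec: SyntheticFieldSpec, in_field: np.ndarray) -> np.ndarray:
    """Smooth wavy horizontal bands, quantile-cut into equal-count strata."""
    h, w = spec.height_px, spec.width_px
    amp = spec.band_wave_amplitude_px
    if amp is None:
        amp = h / 8.0
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    t = rr + amp * np.sin(2 * np.pi * 2 * cc / w)
    strata = np.full((h, w), -1, dtype=np.int16)
    vals = t[in_field]
    edges = np.quantile(vals, np.linspace(0, 1, spec.n_strata + 1)[1:-1])
    strata[in_field] = np.searchsorted(edges, vals, side="right")
    return strata


def _place_damage(spec: SyntheticFieldSpec, in_field: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Union of seeded circular patches covering ≈ damage_fraction of the field."""
    damage = np.zeros(in_field.shape, dtype=bool)
    n_field = int(in_field.sum())
    target = int(round(spec.damage_fraction * n_field))
    if target == 0:
        return damage
    r = spec.damage_patch_radius_px
    if r < 1:
        raise ValueError("damage_patch_radius_px must be ≥ 1")
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = dy ** 2 + dx ** 2 <= r ** 2
    h, w = in_field.shape
    attempts = 0
    max_patches = max(1000, 20 * target // max(int(disk.sum()), 1))
    while int(damage.sum()) < target:
        attempts += 1
        if attempts > max_patches:
            raise ValueError(
                f"damage_fraction {spec.damage_fraction} infeasible with "
                f"patch radius {r} on this field")
        # center drawn among still-undamaged field pixels: guarantees progress
        candidates = np.flatnonzero((in_field & ~damage).ravel())
        idx = rng.choice(candidates)
        cy, cx = divmod(int(idx), w)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        sub = disk[(y0 - cy + r):(y1 - cy + r), (x0 - cx + r):(x1 - cx + r)]
        # clip to the field as we go so coverage counts in-field pixels only
        damage[y0:y1, x0:x1] |= sub & in_field[y0:y1, x0:x1]
    return damage


def generate_field(spec: SyntheticFieldSpec) -> SyntheticField:
    """Render a georeferenced synthetic field with ground truth.

    Deterministic per seed: two runs with the same spec produce bit-identical
    rasters.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    inset = spec.boundary_inset_px
    transform = GridTransform(x0=spec.origin[0], y0=spec.origin[1],
                              sx=spec.pixel_size_m, sy=spec.pixel_size_m)
    minx, miny, maxx, maxy = transform.extent((h, w))
    d = inset * spec.pixel_size_m
    boundary = FieldBoundary(box(minx + d, miny + d, maxx - d, maxy - d),
                             crs=CRS(epsg=spec.epsg))

    in_field = np.zeros((h, w), dtype=bool)
    in_field[inset:h - inset, inset:w - inset] = True

    strata = _stratum_layout(spec, in_field)
    damage = _place_damage(spec, in_field, rng)

    dn_max = 2 ** spec.bit_depth - 1
    scale = dn_max / 255.0  # stratum tables are specified on the 8-bit scale
    bands = np.zeros((3, h, w), dtype=np.float64)
    for s, rgb in enumerate(spec.stratum_rgb):
        sel = strata == s
        for ch in range(3):
            bands[ch, sel] = rgb[ch] * scale
    for ch, delta in enumerate(spec.damage_rgb_delta):
        bands[ch, damage] += delta * scale
    bands += rng.normal(0.0, spec.noise_sd * scale, size=bands.shape)
    bands = np.clip(np.rint(bands), 1, dn_max)  # keep in-field DNs off the 0 nodata value
    bands[:, ~in_field] = 0
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    bands = bands.astype(dtype)

    ortho = RGBOrthomosaic(bands=bands, transform=transform,
                           crs=CRS(epsg=spec.epsg), nodata_mask=~in_field,
                           nodata=0)
    return SyntheticField(ortho=ortho, boundary=boundary, strata=strata,
                          damage_mask=damage, spec=spec)


def end_to_end_fixture(spec: SyntheticFieldSpec, outdir,
                       n_points: int = 100, min_spacing_m: float = 15.0,
                       point_seed: int = 45):
    """Write every file the CLI consumes: GeoTIFF, boundary GeoJSON and a
    reference-label CSV whose labels come from the ground-truth strata.

    Returns the paths ``(orthomosaic, boundary, reference_csv)`` plus the
    generated :class:`SyntheticField`.
    """
    from .validation import sample_points

    os.makedirs(outdir, exist_ok=True)
    fieldset = generate_field(spec)
    ortho_path = os.path.join(outdir, "orthomosaic.tif")
    boundary_path = os.path.join(outdir, "boundary.geojson")
    csv_path = os.path.join(outdir, "reference_labels.csv")
    write_orthomosaic(ortho_path, fieldset.ortho)
    write_boundary(boundary_path, fieldset.boundary)

    pts = sample_points(fieldset.boundary, n=n_points,
                        min_spacing_m=min_spacing_m, seed=point_seed)
    rows, cols = fieldset.ortho.transform.point_to_rowcol(pts[:, 0], pts[:, 1])
    labels = fieldset.strata[rows, cols]
    with open(csv_path, "w") as fh:
        fh.write("x,y,label\n")
        for (x, y), lab in zip(pts, labels):
            fh.write(f"{x:.3f},{y:.3f},{int(lab)}\n")
    return (ortho_path, boundary_path, csv_path), fieldset
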