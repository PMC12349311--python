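"""RGB vegetation indices: ExG, GLI, MGRVI and their composite mean.

The three indices are the biophysical feature basis of the whole method:

    ExG   = 2g − r − b                      (range [−2, 2] on [0,1] channels)
    GLI   = (2g − r − b) / (2g + r + b)     (range [−1, 1])
    MGRVI = (g² − r²) / (g² + r²)           (range [−1, 1])

computed on channels rescaled to [0, 1] by bit-depth division.  Pixels with a
zero index denominator (e.g. pure black) are marked invalid rather than
zero-filled, so shadow artefacts cannot masquerade as damage.  The composite
is the pixel-wise mean of the three indices after each is min–max rescaled
to [0, 1] over valid field pixels — the rescaling balances ExG's wider
native range against the two normalized indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridTransform, RGBOrthomosaic

INDEX_NAMES = ("exg", "gli", "mgrvi")


@dataclass
class IndexStack:
    """Aligned per-pixel index grids plus the [0, 1] composite."""

    exg: np.ndarray
    gli: np.ndarray
    mgrvi: np.ndarray
    composite: np.ndarray
    valid_mask: np.ndarray
    transform: GridTransform | None = None
    crs: object | None = None

    def feature_matrix(self) -> np.ndarray:
        """(n_valid, 3) feature matrix in INDEX_NAMES order (row-major pixel order)."""
        return np.column_stack([g[self.valid_mask] for g in (self.exg, self.gli, self.mgrvi)])


def normalize_channels(ortho: RGBOrthomosaic, scale: float | None = None):
    """Rescale digital numbers to [0, 1] by dividing by (2^bitdepth − 1).

    Float rasters carry no bit depth; pass ``scale`` explicitly for those.
    Returns ``(r, g, b)`` float64 grids; nodata pixels hold NaN.
    """
    if scale is None:
        depth = ortho.bit_depth
        if depth is None:
            raise ValueError(
                "unknown bit depth for float raster: pass an explicit scale "
                "(e.g. scale=255 for data digitized from 8-bit)")
        scale = float(2 ** depth - 1)
    out = ortho.bands.astype(np.float64) / scale
    out[:, ortho.nodata_mask] = np.nan
    return out[0], out[1], out[2]


def compute_index(name: str, r: np.ndarray, g: np.ndarray, b: np.ndarray,
                  exg_chromatic: bool = False) -> np.ndarray:
    """One vegetation index on [0, 1] channels; NaN where undefined.

    ``exg_chromatic`` computes ExG on chromatic coordinates
    r/(r+g+b) etc. instead of the rescaled channels themselves.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if name == "exg":
            if exg_chromatic:
                s = r + g + b
                return np.where(s != 0, (2 * g - r - b) / s, np.nan)
            return 2 * g - r - b
        if name == "gli":
            den = 2 * g + r + b
            return np.where(den != 0, (2 * g - r - b) / den, np.nan)
        if name == "mgrvi":
            den = g ** 2 + r ** 2
            return np.where(den != 0, (g ** 2 - r ** 2) / den, np.nan)
    raise ValueError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")


def _rescale01(grid: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Min–max rescale over valid pixels; a constant grid maps to 0.5."""
    vals = grid[valid]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full_like(grid, np.nan)
    if hi > lo:
        out[valid] = (grid[valid] - lo) / (hi - lo)
    else:
        out[valid] = 0.5
    return out


def compute_composite(exg, gli, mgrvi, valid_mask, rescale: bool = True) -> np.ndarray:
    """Mean vegetation index in [0, 1] used to rank pixel vigor.

    With ``rescale`` (default) each index is min–max rescaled over valid
    pixels before averaging, so no index dominates by native range; without
    it the raw indices are averaged first and the mean is rescaled, which
    reproduces a plain "average index value" ranking.
    """
    if not valid_mask.any():
        raise ValueError("no valid pixels to compute composite over")
    if rescale:
        parts = [_rescale01(g, valid_mask) for g in (exg, gli, mgrvi)]
        comp = (parts[0] + parts[1] + parts[2]) / 3.0
    else:
        raw = (np.asarray(exg) + np.asarray(gli) + np.asarray(mgrvi)) / 3.0
        comp = _rescale01(raw, valid_mask)
    comp[~valid_mask] = np.nan
    return comp


def compute_index_stack(ortho: RGBOrthomosaic, rescale: bool = True,
                        exg_chromatic: bool = False,
                        scale: float | None = None) -> IndexStack:
    """Full feature stack for a clipped orthomosaic."""
    r, g, b = normalize_channels(ortho, scale=scale)
    exg = compute_index("exg", r, g, b, exg_chromatic=exg_chromatic)
    gli = compute_index("gli", r, g, b)
    mgrvi = compute_index("mgrvi", r, g, b)
    valid = ortho.valid_mask & np.isfinite(exg) & np.isfinite(gli) & np.isfinite(mgrvi)
    composite = compute_composite(exg, gli, mgrvi, valid, rescale=rescale)
    for grid in (exg, gli, mgrvi):
        grid[~valid] = np.nan
    return IndexStack(exg=exg, gli=gli, mgrvi=mgrvi, composite=composite,
                      valid_mask=valid, transform=ortho.transform, crs=ortho.crs)
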