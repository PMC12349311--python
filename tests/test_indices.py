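"""Vegetation index formulas, ranges, invariances and the composite mean."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigormap import compute_composite, compute_index, normalize_channels
from vigormap.indices import compute_index_stack
from vigormap.raster import CRS, GridTransform, RGBOrthomosaic

channel = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
positive_channel = st.floats(min_value=1e-6, max_value=1.0)


def _ortho_from(bands, nodata=None):
    bands = np.asarray(bands)
    return RGBOrthomosaic(bands=bands,
                          transform=GridTransform(0, 10, 1, 1),
                          crs=CRS(epsg=2180),
                          nodata_mask=np.zeros(bands.shape[1:], dtype=bool),
                          nodata=nodata)


class TestNormalization:
    @pytest.mark.parametrize("dtype, value, expected", [
        (np.uint8, 255, 1.0),
        (np.uint8, 0, 0.0),
        (np.uint16, 32768, 32768 / 65535),
    ])
    def test_bit_depth_division(self, dtype, value, expected):
        ortho = _ortho_from(np.full((3, 2, 2), value, dtype=dtype))
        r, g, b = normalize_channels(ortho)
        assert r[0, 0] == pytest.approx(expected)

    def test_float_raster_needs_explicit_scale(self):
        ortho = _ortho_from(np.full((3, 2, 2), 0.5, dtype=np.float32))
        with pytest.raises(ValueError, match="scale"):
            normalize_channels(ortho)
        r, _, _ = normalize_channels(ortho, scale=1.0)
        assert r[0, 0] == pytest.approx(0.5)

    def test_nodata_propagates_as_nan(self):
        ortho = _ortho_from(np.full((3, 2, 2), 10, dtype=np.uint8))
        ortho.nodata_mask[0, 0] = True
        r, _, _ = normalize_channels(ortho)
        assert np.isnan(r[0, 0]) and np.isfinite(r[1, 1])


class TestIndexFormulas:
    @pytest.mark.parametrize("name, rgb, expected", [
        ("gli", (0.2, 0.6, 0.2), 0.5),          # 0.8 / 1.6
        ("mgrvi", (0.4, 0.4, 0.9), 0.0),        # r = g symmetry
        ("exg", (0.1, 0.9, 0.1), 1.6),
    ])
    def test_hand_worked_values(self, name, rgb, expected):
        r, g, b = (np.array([v]) for v in rgb)
        assert compute_index(name, r, g, b)[0] == pytest.approx(expected)

    def test_zero_denominator_marks_invalid(self):
        z = np.array([0.0])
        assert np.isnan(compute_index("gli", z, z, z)[0])
        assert np.isnan(compute_index("mgrvi", z, z, z)[0])

    def test_unknown_index_name(self):
        one = np.array([0.5])
        with pytest.raises(ValueError, match="unknown index"):
            compute_index("vari", one, one, one)

    @settings(max_examples=200, derandomize=True)
    @given(r=channel, g=channel, b=channel)
    def test_ranges_on_unit_channels(self, r, g, b):
        r, g, b = np.array([r]), np.array([g]), np.array([b])
        exg = compute_index("exg", r, g, b)[0]
        assert -2.0 <= exg <= 2.0
        gli = compute_index("gli", r, g, b)[0]
        if np.isfinite(gli):
            assert -1.0 - 1e-12 <= gli <= 1.0 + 1e-12
        mgrvi = compute_index("mgrvi", r, g, b)[0]
        if np.isfinite(mgrvi):
            assert -1.0 - 1e-12 <= mgrvi <= 1.0 + 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(r=positive_channel, g=positive_channel, b=positive_channel,
           k=st.floats(min_value=0.1, max_value=0.99))
    def test_brightness_invariance(self, r, g, b, k):
        """GLI and MGRVI are ratios: uniform scaling cancels; ExG scales by k."""
        args = tuple(np.array([v]) for v in (r, g, b))
        scaled = tuple(a * k for a in args)
        for name in ("gli", "mgrvi"):
            assert compute_index(name, *scaled)[0] == pytest.approx(
                compute_index(name, *args)[0], abs=1e-9)
        assert compute_index("exg", *scaled)[0] == pytest.approx(
            k * compute_index("exg", *args)[0], abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(r=positive_channel, g=positive_channel, b=positive_channel,
           dg=st.floats(min_value=1e-6, max_value=0.5))
    def test_monotone_in_green(self, r, g, b, dg):
        args = tuple(np.array([v]) for v in (r, g, b))
        up = (args[0], args[1] + dg, args[2])
        for name in ("exg", "gli", "mgrvi"):
            assert compute_index(name, *up)[0] >= compute_index(name, *args)[0] - 1e-12


class TestComposite:
    def test_rescale_endpoints_and_midpoint(self):
        # three pixels: joint field minimum, joint maximum, and a mixed one
        exg = np.array([[-1.0, 1.0, 1.0]])     # mixed pixel at ExG max
        gli = np.array([[-0.5, 0.5, -0.5]])    # ... at GLI min
        mgrvi = np.array([[-0.2, 0.6, 0.2]])   # ... at MGRVI midpoint
        valid = np.ones_like(exg, dtype=bool)
        comp = compute_composite(exg, gli, mgrvi, valid)
        assert comp[0, 0] == pytest.approx(0.0)
        assert comp[0, 1] == pytest.approx(1.0)
        assert comp[0, 2] == pytest.approx((1 + 0 + 0.5) / 3)

    def test_constant_index_contributes_half(self):
        exg = np.array([[0.3, 0.3]])           # constant over the field
        gli = np.array([[-0.5, 0.5]])
        mgrvi = np.array([[-0.2, 0.6]])
        valid = np.ones_like(exg, dtype=bool)
        comp = compute_composite(exg, gli, mgrvi, valid)
        assert comp[0, 0] == pytest.approx((0.5 + 0 + 0) / 3)
        assert comp[0, 1] == pytest.approx((0.5 + 1 + 1) / 3)

    def test_no_valid_pixels_errors(self):
        z = np.zeros((2, 2))
        with pytest.raises(ValueError, match="no valid pixels"):
            compute_composite(z, z, z, np.zeros((2, 2), dtype=bool))

    def test_stack_ranges_on_synthetic_field(self, default_field, pipeline_products):
        _, stack, _, _ = pipeline_products
        v = stack.valid_mask
        assert np.all((stack.gli[v] >= -1) & (stack.gli[v] <= 1))
        assert np.all((stack.mgrvi[v] >= -1) & (stack.mgrvi[v] <= 1))
        assert np.all((stack.exg[v] >= -2) & (stack.exg[v] <= 2))
        assert np.all((stack.composite[v] >= 0) & (stack.composite[v] <= 1))
        # grids aligned and NaN outside the valid mask
        assert np.all(np.isnan(stack.composite[~v]))

    def test_black_pixels_become_invalid_not_damage(self):
        bands = np.full((3, 4, 4), 100, dtype=np.uint8)
        bands[:, 0, 0] = 0  # a shadow/black pixel
        ortho = _ortho_from(bands)
        stack = compute_index_stack(ortho)
        assert not stack.valid_mask[0, 0]
        assert stack.valid_mask[1:].all()
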