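import numpy as np
import pytest

from vigormap import (clip_to_boundary, compute_index_stack, detect_damage,
                      classify_vigor, generate_field, SyntheticFieldSpec)


@pytest.fixture(scope="session")
def default_field():
    """Desk-scale synthetic maize field with planted damage (seed 7)."""
    return generate_field(SyntheticFieldSpec(seed=7))


@pytest.fixture(scope="session")
def pipeline_products(default_field):
    """Clipped raster, index stack, vigor classes and default damage masks."""
    f = default_field
    clipped = clip_to_boundary(f.ortho, f.boundary)
    stack = compute_index_stack(clipped)
    vcr = classify_vigor(stack, seed=42)
    masks = detect_damage(stack.composite, vcr)
    return clipped, stack, vcr, masks
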