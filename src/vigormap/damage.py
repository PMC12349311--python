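"""Class-conditional quantile damage masking.

Within each vigor class the weakest fraction of pixels by composite index
(default 25%) is flagged as potentially damaged; the five per-class masks
are unioned into the final binary damage raster.  Selection is rank-based:
exactly ``floor(fraction × class_size)`` pixels are flagged — the lowest-
composite ones, ties broken by row-major pixel order — so flagged counts are
deterministic and nested across fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vigor import VigorClassRaster


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-class flagged fractions, each within [0, 1]."""

    fraction_by_class: tuple = (0.25, 0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        fr = tuple(float(f) for f in self.fraction_by_class)
        for f in fr:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"threshold fraction {f} outside [0.0, 1.0]")
        object.__setattr__(self, "fraction_by_class", fr)

    @classmethod
    def uniform(cls, fraction: float = 0.25, n_classes: int = 5) -> "ThresholdConfig":
        return cls(fraction_by_class=(fraction,) * n_classes)


@dataclass
class DamageMaskSet:
    """Per-class binary masks, their union, and exact flagged counts."""

    per_class: list                     # k boolean grids, pairwise disjoint
    aggregated: np.ndarray
    flagged_counts: np.ndarray          # ints, flagged_counts[i] = floor(f_i * n_i)
    config: ThresholdConfig = field(default_factory=ThresholdConfig)


def detect_class_damage(composite: np.ndarray, vigor: VigorClassRaster,
                        class_id: int, fraction: float):
    """Flag the ``floor(fraction × n)`` lowest-composite pixels of one class.

    Returns ``(mask, flagged_count)``.  Ties in the composite resolve by
    row-major pixel order (stable sort over flat indices), so re-runs are
    bit-identical.  An empty class yields an empty mask.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0.0, 1.0]")
    if not 0 <= class_id < vigor.n_classes:
        raise ValueError(f"class_id {class_id} outside 0..{vigor.n_classes - 1}")
    mask = np.zeros(vigor.labels.shape, dtype=bool)
    flat_idx = np.flatnonzero((vigor.labels == class_id).ravel())
    n = len(flat_idx)
    m = int(np.floor(fraction * n))
    if m > 0:
        vals = composite.ravel()[flat_idx]
        order = np.argsort(vals, kind="stable")  # flat_idx ascending => row-major ties
        mask.ravel()[flat_idx[order[:m]]] = True
    return mask, m


def aggregate_masks(per_class) -> np.ndarray:
    """Pixel-wise union of the per-class masks."""
    shapes = {m.shape for m in per_class}
    if len(shapes) != 1:
        raise ValueError(f"masks are misaligned: shapes {sorted(shapes)}")
    out = np.zeros(per_class[0].shape, dtype=bool)
    for m in per_class:
        out |= m
    return out


def detect_damage(composite: np.ndarray, vigor: VigorClassRaster,
                  config: ThresholdConfig | None = None) -> DamageMaskSet:
    """Run class-conditional damage detection for every vigor class."""
    config = config or ThresholdConfig()
    if len(config.fraction_by_class) != vigor.n_classes:
        raise ValueError("one threshold fraction per vigor class required")
    masks, counts = [], []
    for cid, frac in enumerate(config.fraction_by_class):
        m, c = detect_class_damage(composite, vigor, cid, frac)
        masks.append(m)
        counts.append(c)
    return DamageMaskSet(per_class=masks, aggregated=aggregate_masks(masks),
                         flagged_counts=np.array(counts), config=config)


def retune(vigor: VigorClassRaster, composite: np.ndarray,
           new_config: ThresholdConfig) -> DamageMaskSet:
    """Re-run detection with adjusted per-class fractions.

    The interactive tuning loop of the field workflow, realized as a pure
    function: the result depends only on (vigor, composite, new_config).
    """
    return detect_damage(composite, vigor, new_config)


def diff_counts(old: DamageMaskSet, new: DamageMaskSet) -> list[tuple[int, int, int]]:
    """(class_id, old_count, new_count) for classes whose mask changed size."""
    return [(cid, int(o), int(n))
            for cid, (o, n) in enumerate(zip(old.flagged_counts, new.flagged_counts))
            if o != n]
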