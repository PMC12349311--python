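"""Area statistics: per-class crop and damage areas in hectares and shares.

Areas come straight from pixel counts (count × pixel area); shares are
computed against the total field area so the per-class shares sum to the
total damage share.  Rounding (2 decimals for hectares, 1 for percent,
half-up) is applied only at display time — raw values are always kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .damage import DamageMaskSet
from .vigor import CLASS_NAMES, VigorClassRaster

M2_PER_HA = 10_000.0


@dataclass
class ClassArea:
    class_name: str
    crop_area_ha: float
    damage_area_ha: float
    damage_share_pct: float


@dataclass
class AreaSummary:
    total_field_ha: float
    per_class: list            # of ClassArea
    total_damage_ha: float
    total_damage_pct: float

    @classmethod
    def from_damage_areas(cls, damage_ha, total_field_ha, crop_ha=None,
                          class_names=CLASS_NAMES) -> "AreaSummary":
        """Build a summary from per-class damage areas already in hectares."""
        damage_ha = [float(d) for d in damage_ha]
        if crop_ha is None:
            crop_ha = [float("nan")] * len(damage_ha)
        per_class = [
            ClassArea(name, c, d, 100.0 * d / total_field_ha)
            for name, c, d in zip(class_names, crop_ha, damage_ha)
        ]
        total = sum(damage_ha)
        return cls(total_field_ha=float(total_field_ha), per_class=per_class,
                   total_damage_ha=total,
                   total_damage_pct=100.0 * total / total_field_ha)


def summarize(vigor: VigorClassRaster, masks: DamageMaskSet,
              pixel_area_m2: float, field_area_m2: float | None = None) -> AreaSummary:
    """Headline quantities: class areas, damage areas (ha) and shares (%).

    ``field_area_m2`` defaults to valid-pixel count × pixel area (the
    rasterized field); pass the boundary polygon's area to report shares
    against the surveyed area instead.
    """
    if pixel_area_m2 <= 0:
        raise ValueError("pixel area must be positive")
    sizes = vigor.class_sizes()
    n_valid = int(sizes.sum())
    if n_valid == 0:
        raise ValueError("zero valid pixels: nothing to summarize")
    if field_area_m2 is None:
        field_area_m2 = n_valid * pixel_area_m2
    total_field_ha = field_area_m2 / M2_PER_HA
    crop_ha = sizes * pixel_area_m2 / M2_PER_HA
    damage_ha = masks.flagged_counts * pixel_area_m2 / M2_PER_HA
    return AreaSummary.from_damage_areas(
        damage_ha, total_field_ha, crop_ha=crop_ha,
        class_names=vigor.class_names[:vigor.n_classes])


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up (2.86 → 2.9 at 1 decimal), for display only."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_summary_table(summary: AreaSummary) -> list[tuple[str, str, str]]:
    """Display rows (class, damage ha to 2 dp, share % to 1 dp) plus a Total row."""
    rows = [(ca.class_name,
             f"{round_half_up(ca.damage_area_ha, 2):.2f}",
             f"{round_half_up(ca.damage_share_pct, 1):.1f}")
            for ca in summary.per_class]
    rows.append(("Total",
                 f"{round_half_up(summary.total_damage_ha, 2):.2f}",
                 f"{round_half_up(summary.total_damage_pct, 1):.1f}"))
    return rows


def to_frame(summary: AreaSummary) -> pd.DataFrame:
    """Machine-readable table: display columns plus raw (unrounded) columns."""
    rows = []
    for ca in summary.per_class:
        rows.append({
            "class": ca.class_name,
            "crop_area_ha": round_half_up(ca.crop_area_ha, 2),
            "damage_area_ha": round_half_up(ca.damage_area_ha, 2),
            "damage_share_pct": round_half_up(ca.damage_share_pct, 1),
            "raw_crop_area_ha": ca.crop_area_ha,
            "raw_damage_area_ha": ca.damage_area_ha,
            "raw_damage_share_pct": ca.damage_share_pct,
        })
    rows.append({
        "class": "Total",
        "crop_area_ha": round_half_up(summary.total_field_ha, 2),
        "damage_area_ha": round_half_up(summary.total_damage_ha, 2),
        "damage_share_pct": round_half_up(summary.total_damage_pct, 1),
        "raw_crop_area_ha": summary.total_field_ha,
        "raw_damage_area_ha": summary.total_damage_ha,
        "raw_damage_share_pct": summary.total_damage_pct,
    })
    return pd.DataFrame(rows)
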