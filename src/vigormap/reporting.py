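"""Report rendering: technical HTML and interpretive Markdown documents.

Every number printed in a report is read back from the machine-readable
outputs in the run directory (``area_summary.csv``, ``validation_report.csv``)
rather than recomputed, so reports can never drift from the exported tables.
The interpretive report is emitted as Markdown; its content contract —
identification block, area statistics, per-class damage table, graphical
attachments — is format-independent.
"""

from __future__ import annotations

import os
from string import Template

import numpy as np
import pandas as pd

_HTML = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Crop damage report — $field_name</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 60em; }
table { border-collapse: collapse; margin: 1em 0; }
td, th { border: 1px solid #999; padding: 0.3em 0.8em; text-align: right; }
th, td:first-child { text-align: left; }
img { max-width: 100%; margin: 0.5em 0; }
pre { background: #f4f4f4; padding: 1em; overflow-x: auto; }
</style></head><body>
<h1>UAV crop damage assessment — technical report</h1>
<table>
<tr><th>Field</th><td>$field_name</td></tr>
<tr><th>Location</th><td>$location</td></tr>
<tr><th>UAV flight date</th><td>$flight_date</td></tr>
<tr><th>Institution</th><td>$institution</td></tr>
<tr><th>Generated</th><td>$timestamp</td></tr>
</table>
<h2>Damage by crop vigor class</h2>
$area_table
<h2>Damage distribution</h2>
<img src="damage_chart.png" alt="per-class damage chart">
<h2>Damage masks</h2>
<img src="preview_damage.png" alt="aggregated damage mask preview">
<img src="preview_classes.png" alt="vigor class preview">
$validation_section
<h2>Configuration</h2>
<pre>$config_dump</pre>
</body></html>
""")

_MD = Template("""# Crop damage assessment — interpretive report

| | |
|---|---|
| Field | $field_name |
| Location | $location |
| UAV flight date | $flight_date |
| Institution | $institution |
| Generated | $timestamp |

## Crop and damage area statistics

Total field area: **$total_field_ha ha**.
Detected damage: **$total_damage_ha ha** (**$total_damage_pct%** of the field).

$area_table

## Graphical attachments

![per-class damage chart](damage_chart.png)
![aggregated damage mask](preview_damage.png)
![vigor classification](preview_classes.png)
""")


def _df_to_html(df: pd.DataFrame) -> str:
    head = "".join(f"<th>{c}</th>" for c in df.columns)
    body = "".join(
        "<tr>" + "".join(f"<td>{v}</td>" for v in row) + "</tr>"
        for row in df.itertuples(index=False))
    return f"<table><tr>{head}</tr>{body}</table>"


def _df_to_md(df: pd.DataFrame) -> str:
    lines = ["| " + " | ".join(str(c) for c in df.columns) + " |",
             "|" + "---|" * len(df.columns)]
    for row in df.itertuples(index=False):
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def damage_chart(workdir) -> None:
    """Bar chart of per-class damage area, read from area_summary.csv."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .vigor import CLASS_COLORS

    df = pd.read_csv(os.path.join(workdir, "area_summary.csv"))
    per_class = df[df["class"] != "Total"]
    colors = [tuple(c / 255 for c in rgb) for rgb in CLASS_COLORS[:len(per_class)]]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(per_class["class"], per_class["damage_area_ha"], color=colors,
           edgecolor="black", linewidth=0.5)
    ax.set_ylabel("Damage area (ha)")
    ax.set_title("Detected damage by crop vigor class")
    fig.tight_layout()
    fig.savefig(os.path.join(workdir, "damage_chart.png"), dpi=120,
                metadata={"Software": None})
    plt.close(fig)


def previews(workdir, clipped, vcr, masks) -> None:
    """Quick-look PNGs of the class map and aggregated damage mask."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    from .vigor import CLASS_COLORS

    cmap = ListedColormap([tuple(c / 255 for c in rgb)
                           for rgb in CLASS_COLORS[:vcr.n_classes]])
    lab = np.ma.masked_where(~vcr.valid_mask, vcr.labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(lab, cmap=cmap, vmin=0, vmax=vcr.n_classes - 1, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(os.path.join(workdir, "preview_classes.png"), dpi=110,
                bbox_inches="tight", metadata={"Software": None})
    plt.close(fig)

    rgb = np.moveaxis(clipped.bands[:3], 0, -1).astype(float)
    denom = max(float(rgb.max()), 1.0)
    rgb = rgb / denom
    overlay = rgb.copy()
    overlay[masks.aggregated] = (1.0, 0.0, 0.0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(overlay, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(os.path.join(workdir, "preview_damage.png"), dpi=110,
                bbox_inches="tight", metadata={"Software": None})
    plt.close(fig)


def render_reports(workdir, manifest, clipped, vcr, masks, timestamp=None) -> None:
    """Write report.html and report.md from the run directory's tables."""
    damage_chart(workdir)
    previews(workdir, clipped, vcr, masks)

    df = pd.read_csv(os.path.join(workdir, "area_summary.csv"))
    display = df[["class", "damage_area_ha", "damage_share_pct"]].rename(columns={
        "class": "Crop Vigor Class", "damage_area_ha": "Damage Area (ha)",
        "damage_share_pct": "Damage Share (%)"})
    display = display.copy()
    display["Damage Area (ha)"] = display["Damage Area (ha)"].map("{:.2f}".format)
    display["Damage Share (%)"] = display["Damage Share (%)"].map("{:.1f}".format)

    validation_html = ""
    val_csv = os.path.join(workdir, "validation_report.csv")
    if os.path.exists(val_csv):
        vdf = pd.read_csv(val_csv)
        validation_html = ("<h2>Accuracy assessment</h2>" + _df_to_html(vdf) +
                           '<img src="confusion_matrix.png" alt="confusion matrix">')

    import json
    total = df[df["class"] == "Total"].iloc[0]
    ts = timestamp or manifest.stages.get("report") or ""
    context = dict(
        field_name=manifest.field_name or "(unnamed)",
        location=manifest.location, flight_date=manifest.flight_date,
        institution=manifest.institution, timestamp=ts,
        config_dump=json.dumps(manifest.config, indent=2, sort_keys=True),
        area_table=_df_to_html(display), validation_section=validation_html)
    with open(os.path.join(workdir, "report.html"), "w") as fh:
        fh.write(_HTML.substitute(context))

    md_context = dict(
        field_name=manifest.field_name or "(unnamed)",
        location=manifest.location, flight_date=manifest.flight_date,
        institution=manifest.institution, timestamp=ts,
        total_field_ha=f"{float(total['crop_area_ha']):.2f}",
        total_damage_ha=f"{float(total['damage_area_ha']):.2f}",
        total_damage_pct=f"{float(total['damage_share_pct']):.1f}",
        area_table=_df_to_md(display))
    with open(os.path.join(workdir, "report.md"), "w") as fh:
        fh.write(_MD.substitute(md_context))
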