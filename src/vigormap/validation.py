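"""Map-accuracy assessment with spatially constrained random sampling.

Reference points are placed uniformly inside the field boundary subject to a
minimum pairwise spacing (seeded rejection sampling), compared against the
class raster at the same locations, and summarized as a 5×5 confusion matrix
with per-class precision/recall/F1/support, overall accuracy and
macro/weighted averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .raster import FieldBoundary, GridTransform
from .vigor import CLASS_NAMES, NODATA_LABEL, VigorClassRaster

log = logging.getLogger(__name__)


class SamplingError(RuntimeError):
    pass


@dataclass
class ValidationPointSet:
    points: np.ndarray                  # (n, 2) x, y in CRS metres
    reference_labels: np.ndarray
    predicted_labels: np.ndarray
    seed: int
    min_spacing_m: float


@dataclass
class ClassificationReport:
    confusion: np.ndarray               # (k, k); rows = reference, cols = predicted
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    overall_accuracy: float
    macro_avg: dict
    weighted_avg: dict
    class_names: tuple = CLASS_NAMES
    undefined_precision: np.ndarray = field(default=None)  # cols with no predictions
    undefined_recall: np.ndarray = field(default=None)     # rows with no references


def sample_points(boundary: FieldBoundary, n: int = 100,
                  min_spacing_m: float = 15.0, seed: int = 45,
                  max_attempts: int | None = None) -> np.ndarray:
    """Uniform random points inside the boundary, ≥ ``min_spacing_m`` apart.

    Seeded rejection sampling: candidates drawn uniformly over the bounding
    box are accepted iff inside the polygon and at least the minimum spacing
    from every previously accepted point.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if min_spacing_m < 0:
        raise ValueError("min_spacing_m must be ≥ 0")
    if max_attempts is None:
        max_attempts = 10_000 * n
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = boundary.geometry.bounds
    accepted = np.empty((0, 2))
    d2 = min_spacing_m ** 2
    attempts = 0
    batch = max(64, n)
    while len(accepted) < n and attempts < max_attempts:
        take = min(batch, max_attempts - attempts)
        xs = rng.uniform(minx, maxx, take)
        ys = rng.uniform(miny, maxy, take)
        attempts += take
        inside = shapely.contains_xy(boundary.geometry, xs, ys)
        for x, y in zip(xs[inside], ys[inside]):
            if len(accepted) and (((accepted[:, 0] - x) ** 2 +
                                   (accepted[:, 1] - y) ** 2).min() < d2):
                continue
            accepted = np.vstack([accepted, (x, y)])
            if len(accepted) == n:
                break
    if len(accepted) < n:
        raise SamplingError(
            f"could only place {len(accepted)} of {n} points with "
            f"{min_spacing_m} m spacing after {max_attempts} attempts")
    return accepted


def extract_labels(vigor: VigorClassRaster, transform: GridTransform,
                   points: np.ndarray):
    """Class label of the pixel containing each point.

    Points exactly on a pixel edge resolve to the upper-left pixel.  Points
    on nodata cells (or outside the grid) are recorded as missing: returns
    ``(labels, kept_mask)`` with nodata points excluded from ``labels`` and
    a warning logged.
    """
    points = np.asarray(points, dtype=float)
    rows, cols = transform.point_to_rowcol(points[:, 0], points[:, 1])
    h, w = vigor.labels.shape
    in_grid = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    labels = np.full(len(points), NODATA_LABEL, dtype=int)
    labels[in_grid] = vigor.labels[rows[in_grid], cols[in_grid]]
    kept = labels != NODATA_LABEL
    n_missing = int((~kept).sum())
    if n_missing:
        log.warning("%d point(s) fell on nodata cells and were excluded", n_missing)
    return labels[kept], kept


def build_report(reference, predicted, n_classes: int = 5,
                 class_names=CLASS_NAMES) -> ClassificationReport:
    """Confusion matrix and standard classification metrics.

    Precision/recall of a class with no predictions/references is reported
    as 0 and flagged; macro averages include those zeros.
    """
    reference = np.asarray(reference, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if reference.shape != predicted.shape or reference.ndim != 1:
        raise ValueError("reference and predicted must be equal-length 1-D label lists")
    if len(reference) == 0:
        raise ValueError("empty label lists")
    labels = np.arange(n_classes)
    for arr, what in ((reference, "reference"), (predicted, "predicted")):
        bad = np.setdiff1d(np.unique(arr), labels)
        if bad.size:
            raise ValueError(f"{what} labels outside 0..{n_classes - 1}: {bad.tolist()}")

    cm = _sk_confusion(reference, predicted, labels=labels)
    precision, recall, f1, support = _sk_prfs(
        reference, predicted, labels=labels, zero_division=0)
    accuracy = float(np.trace(cm)) / len(reference)
    macro = {"precision": float(precision.mean()), "recall": float(recall.mean()),
             "f1": float(f1.mean())}
    weights = support / support.sum()
    weighted = {"precision": float((precision * weights).sum()),
                "recall": float((recall * weights).sum()),
                "f1": float((f1 * weights).sum())}
    return ClassificationReport(
        confusion=cm, precision=precision, recall=recall, f1=f1,
        support=support, overall_accuracy=accuracy,
        macro_avg=macro, weighted_avg=weighted,
        class_names=tuple(class_names)[:n_classes],
        undefined_precision=(cm.sum(axis=0) == 0),
        undefined_recall=(cm.sum(axis=1) == 0))


def report_to_frame(report: ClassificationReport) -> pd.DataFrame:
    """Table 8-style metric table, 3-decimal display rounding."""
    rows = [{"class": name,
             "precision": round(float(p), 3), "recall": round(float(r), 3),
             "f1": round(float(f), 3), "support": int(s)}
            for name, p, r, f, s in zip(report.class_names, report.precision,
                                        report.recall, report.f1, report.support)]
    rows.append({"class": "Overall Accuracy", "precision": None, "recall": None,
                 "f1": round(report.overall_accuracy, 3),
                 "support": int(report.support.sum())})
    for label, avg in (("Macro Avg", report.macro_avg),
                       ("Weighted Avg", report.weighted_avg)):
        rows.append({"class": label,
                     "precision": round(avg["precision"], 3),
                     "recall": round(avg["recall"], 3),
                     "f1": round(avg["f1"], 3),
                     "support": int(report.support.sum())})
    return pd.DataFrame(rows)


def complete_confusion(diagonal, row_sums, col_sums) -> np.ndarray:
    """Reconstruct a feasible confusion matrix from published marginals.

    Published accuracy tables usually print per-class recall/precision and
    supports, which pin down the diagonal and both marginals but not the
    off-diagonal cells.  This fills the off-diagonal mass greedily
    (northwest-corner transportation fill, skipping the diagonal), yielding
    one integer matrix consistent with the marginals.  All derived metrics
    depend only on the diagonal and marginals, so any feasible fill gives
    the same precision/recall/F1/accuracy.
    """
    diagonal = np.asarray(diagonal, dtype=int)
    row_extra = np.asarray(row_sums, dtype=int) - diagonal
    col_extra = np.asarray(col_sums, dtype=int) - diagonal
    if (row_extra < 0).any() or (col_extra < 0).any():
        raise ValueError("marginals smaller than the diagonal")
    if row_extra.sum() != col_extra.sum():
        raise ValueError("row and column off-diagonal totals disagree")
    k = len(diagonal)
    cm = np.diag(diagonal).astype(int)
    col_left = col_extra.copy()
    for i in range(k):
        need = row_extra[i]
        for j in range(k):
            if need == 0:
                break
            if j == i or col_left[j] == 0:
                continue
            put = min(need, col_left[j])
            cm[i, j] += put
            col_left[j] -= put
            need -= put
        if need:
            raise ValueError("marginals admit no feasible off-diagonal fill")
    return cm


def labels_from_confusion(cm: np.ndarray):
    """Expand a confusion matrix into (reference, predicted) label lists."""
    cm = np.asarray(cm, dtype=int)
    ref, pred = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ref.extend([i] * cm[i, j])
            pred.extend([j] * cm[i, j])
    return np.array(ref), np.array(pred)


def points_to_geojson(path, pointset: ValidationPointSet, epsg: int | None = None):
    import json
    feats = []
    for (x, y), ref, pred in zip(pointset.points, pointset.reference_labels,
                                 pointset.predicted_labels):
        feats.append({"type": "Feature",
                      "properties": {"reference": int(ref), "predicted": int(pred)},
                      "geometry": {"type": "Point", "coordinates": [float(x), float(y)]}})
    gj = {"type": "FeatureCollection", "features": feats}
    if epsg:
        gj["crs"] = {"type": "name",
                     "properties": {"name": f"urn:ogc:def:crs:EPSG::{epsg}"}}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def plot_confusion(report: ClassificationReport, path) -> None:
    """Confusion-matrix heatmap (reference rows × predicted columns)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(report.confusion, cmap="Blues")
    k = len(report.class_names)
    ax.set_xticks(range(k), report.class_names, rotation=45, ha="right")
    ax.set_yticks(range(k), report.class_names)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("Reference")
    vmax = report.confusion.max() or 1
    for i in range(k):
        for j in range(k):
            v = report.confusion[i, j]
            ax.text(j, i, str(v), ha="center", va="center",
                    color="white" if v > vmax / 2 else "black")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
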