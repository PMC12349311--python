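"""Unsupervised vigor zoning: k-means into five ordered canopy-condition classes.

Valid field pixels are clustered on their (ExG, GLI, MGRVI) feature vectors,
then clusters are relabeled 0..4 by descending mean composite index so that
class 0 is always "Very Good" and class 4 "Very Poor".  The clustering step
is exposed both as a scikit-learn-compatible estimator
(:class:`VigorClassifier`) and as grid-level functions matching the
pipeline's raster flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .indices import IndexStack
from .raster import CRS, GridTransform, write_single_band

CLASS_NAMES = ("Very Good", "Good", "Moderate", "Poor", "Very Poor")
#: display colors per class: bright green, dark green, yellow, orange, red
CLASS_COLORS = ((124, 252, 0), (0, 100, 0), (255, 255, 0), (255, 165, 0), (255, 0, 0))
NODATA_LABEL = -1


@dataclass
class VigorClassRaster:
    """Integer label grid, 0 = best vigor … 4 = worst; −1 outside the field."""

    labels: np.ndarray                  # (rows, cols) int16
    class_mean_composite: np.ndarray    # length-k, non-increasing
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        if np.any(np.diff(self.class_mean_composite) > 1e-12):
            raise AssertionError("class mean composite must be non-increasing with class id")

    @property
    def valid_mask(self):
        return self.labels != NODATA_LABEL

    @property
    def n_classes(self):
        return len(self.class_mean_composite)

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.valid_mask], minlength=self.n_classes)


def _balanced_composite(X: np.ndarray) -> np.ndarray:
    """Default per-point composite: mean of min–max rescaled feature columns."""
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = np.where(hi > lo, (X - lo) / span, 0.5)
    return scaled.mean(axis=1)


def rank_by_composite(raw_labels: np.ndarray, composite: np.ndarray,
                      n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    """Cluster → class mapping by descending mean composite.

    Returns ``(mapping, sorted_means)`` where ``mapping[raw_id]`` is the
    final class id.  Ties break by ascending raw cluster id (stable sort on
    the negated means).
    """
    means = np.array([composite[raw_labels == c].mean() if np.any(raw_labels == c)
                      else -np.inf for c in range(n_clusters)])
    order = np.argsort(-means, kind="stable")  # best vigor first; ties by raw id
    mapping = np.empty(n_clusters, dtype=int)
    mapping[order] = np.arange(n_clusters)
    return mapping, means[order]


class VigorClassifier(ClusterMixin, BaseEstimator):
    """K-means vigor zoning with composite-ordered class labels.

    A thin, reproducible wrapper over :class:`sklearn.cluster.KMeans`
    (k-means++ init, ``n_init`` restarts) that z-standardizes the index
    features, optionally fits on a seeded subsample with nearest-centroid
    assignment of the remainder, and relabels clusters 0..k−1 by strictly
    descending mean composite so label semantics are stable across runs.

    Parameters
    ----------
    n_classes : int, default 5
        Number of vigor classes (the method's contract default).
    random_state : int, default 42
        Seed for centroid initialization and subsampling.
    n_init, max_iter, tol :
        Passed to :class:`~sklearn.cluster.KMeans`.
    standardize : bool, default True
        Z-standardize each feature over the fitted pixels.
    sample_size : int or None
        Fit k-means on at most this many seeded-uniform sampled pixels,
        then assign the rest to the nearest centroid.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Final composite-ordered class labels of the fitted pixels.
    raw_labels_ : ndarray
        K-means labels before vigor ordering.
    mapping_ : ndarray of shape (n_classes,)
        ``mapping_[raw_id] -> class_id``.
    class_mean_composite_ : ndarray, non-increasing
        Mean composite per final class.
    cluster_centers_ : ndarray of shape (n_classes, n_features)
        Centroids in original feature units, ordered by final class id.
    """

    def __init__(self, n_classes: int = 5, random_state: int = 42,
                 n_init: int = 10, max_iter: int = 300, tol: float = 1e-4,
                 standardize: bool = True, sample_size: int | None = None):
        self.n_classes = n_classes
        self.random_state = random_state
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.sample_size = sample_size

    # composite is a per-pixel ranking score; defaults to the scale-balanced
    # mean of the feature columns when not supplied.
    def fit(self, X, y=None, composite: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_pixels, n_features)")
        k = self.n_classes
        if len(X) < k or len(np.unique(X, axis=0)) < k:
            raise ValueError(
                f"need at least {k} distinct feature vectors to form {k} classes")
        if composite is None:
            composite = _balanced_composite(X)
        else:
            composite = np.asarray(composite, dtype=float)
            if composite.shape != (len(X),):
                raise ValueError("composite must be one value per sample")

        if self.standardize:
            self._mean = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sd = np.where(sd > 0, sd, 1.0)
        else:
            self._mean = np.zeros(X.shape[1])
            self._sd = np.ones(X.shape[1])
        Z = (X - self._mean) / self._sd

        km = KMeans(n_clusters=k, init="k-means++", n_init=self.n_init,
                    max_iter=self.max_iter, tol=self.tol,
                    random_state=self.random_state)
        if self.sample_size is not None and len(Z) > self.sample_size:
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(len(Z), size=self.sample_size, replace=False)
            km.fit(Z[idx])
            raw = km.predict(Z)
        else:
            raw = km.fit_predict(Z)

        self.mapping_, self.class_mean_composite_ = rank_by_composite(raw, composite, k)
        self.raw_labels_ = raw
        self.labels_ = self.mapping_[raw]
        centers = km.cluster_centers_ * self._sd + self._mean
        inverse = np.argsort(self.mapping_)
        self.cluster_centers_ = centers[inverse]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Final (vigor-ordered) class of each new feature vector."""
        X = np.asarray(X, dtype=float)
        Z = (X - self._mean) / self._sd
        zc = (self.cluster_centers_ - self._mean) / self._sd
        d2 = ((Z[:, None, :] - zc[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_


def cluster_vigor(stack: IndexStack, k: int = 5, seed: int = 42,
                  **estimator_kwargs) -> np.ndarray:
    """Raw (unordered) k-means labels on the valid pixels of an index stack.

    Returns an int16 grid, −1 outside the valid mask.  Deterministic for a
    fixed seed.
    """
    valid = stack.valid_mask
    if not valid.any():
        raise ValueError("empty valid mask: nothing to cluster")
    X = stack.feature_matrix()
    est = VigorClassifier(n_classes=k, random_state=seed, **estimator_kwargs)
    est.fit(X, composite=stack.composite[valid])
    grid = np.full(valid.shape, NODATA_LABEL, dtype=np.int16)
    grid[valid] = est.raw_labels_
    return grid


def rank_clusters(raw_labels: np.ndarray, composite: np.ndarray,
                  n_clusters: int = 5) -> VigorClassRaster:
    """Relabel raw clusters 0..k−1 by descending mean composite."""
    valid = raw_labels != NODATA_LABEL
    mapping, sorted_means = rank_by_composite(raw_labels[valid], composite[valid],
                                              n_clusters)
    labels = np.full(raw_labels.shape, NODATA_LABEL, dtype=np.int16)
    labels[valid] = mapping[raw_labels[valid]]
    return VigorClassRaster(labels=labels, class_mean_composite=sorted_means)


def classify_vigor(stack: IndexStack, k: int = 5, seed: int = 42,
                   **estimator_kwargs) -> VigorClassRaster:
    """Cluster and rank in one step (the DD_02 classification stage)."""
    raw = cluster_vigor(stack, k=k, seed=seed, **estimator_kwargs)
    return rank_clusters(raw, stack.composite, n_clusters=k)


def write_class_raster(path, vcr: VigorClassRaster,
                       transform: GridTransform, crs: CRS,
                       legend_path=None) -> None:
    """Export as an 8-bit palette GeoTIFF (255 = nodata) plus a legend CSV."""
    grid = np.where(vcr.valid_mask, vcr.labels, 255).astype(np.uint8)
    cmap = np.zeros((3, 256), dtype=np.uint16)
    for cid, rgb in enumerate(CLASS_COLORS[:vcr.n_classes]):
        cmap[:, cid] = [v * 257 for v in rgb]
    write_single_band(path, grid, transform, crs, nodata=255, colormap=cmap)
    if legend_path is not None:
        with open(legend_path, "w") as fh:
            fh.write("class_id,class_name,red,green,blue,mean_composite\n")
            for cid in range(vcr.n_classes):
                r, g, b = CLASS_COLORS[cid]
                fh.write(f"{cid},{vcr.class_names[cid]},{r},{g},{b},"
                         f"{vcr.class_mean_composite[cid]:.6f}\n")
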