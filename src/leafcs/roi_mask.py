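"""ROI mask extraction: k-means on the optimal band, background removal,
8-connected component labeling in row-major order, and ROI areas."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

__all__ = [
    "RoiAreas",
    "cluster_band",
    "extract_primary_mask",
    "label_rois",
    "roi_areas",
]

# 8-connectivity structuring element for component labeling
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class RoiAreas:
    """Pixel bookkeeping for a labeled mask: per-ROI areas, their sum, and
    the whole-image pixel count (total area = sum of the per-ROI areas)."""

    per_roi: dict[int, int]
    total: int
    image: int

    def __post_init__(self) -> None:
        if self.total != sum(self.per_roi.values()):
            raise ValueError("total ROI area must equal the sum of per-ROI areas")
        if self.total > self.image:
            raise ValueError("ROI area cannot exceed image area")


def cluster_band(
    band: np.ndarray, m: int, seed: int = 0
) -> np.ndarray:
    """k-means cluster a single band's intensities into ``m`` classes.

    Classes are renumbered by ascending cluster mean so class 0 is always
    the darkest.  Uses k-means++ initialization with a fixed seed,
    <= 300 iterations, tolerance 1e-4.  ``m=1`` returns an all-zero map.
    """
    band = np.asarray(band)
    if band.size == 0:
        raise ValueError("band is empty")
    if m == 1:
        return np.zeros(band.shape, dtype=np.int32)
    if m < 1:
        raise ValueError(f"class count must be >= 1, got {m}")
    n_distinct = np.unique(band).size
    if m > n_distinct:
        raise ValueError(
            f"cannot split {n_distinct} distinct intensities into {m} classes"
        )
    km = KMeans(
        n_clusters=m,
        init="k-means++",
        n_init=10,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    )
    raw = km.fit_predict(band.reshape(-1, 1).astype(float))
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(m, dtype=np.int32)
    remap[order] = np.arange(m)
    return remap[raw].reshape(band.shape)


def extract_primary_mask(
    class_map: np.ndarray, background_class: int | None = None
) -> np.ndarray:
    """Binary leaf-vs-background mask: everything outside the background
    class.  ``background_class=None`` picks the class with the most pixels
    (leaves occupy a minority of the frame)."""
    class_map = np.asarray(class_map)
    if background_class is None:
        classes, counts = np.unique(class_map, return_counts=True)
        background_class = int(classes[np.argmax(counts)])
    return class_map != background_class


def label_rois(mask: np.ndarray, min_area: int = 16) -> np.ndarray:
    """Label 8-connected components of a binary mask.

    Components smaller than ``min_area`` pixels are dropped (k-means on a
    noisy band produces speckle); survivors are relabeled 1..n in row-major
    first-occurrence order (left to right, top to bottom).
    """
    mask = np.asarray(mask, dtype=bool)
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    raw, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    areas = np.bincount(raw.ravel(), minlength=n + 1)
    keep = np.flatnonzero(areas >= max(min_area, 1))
    keep = keep[keep > 0]
    # order surviving components by first row-major occurrence
    flat = raw.ravel()
    first = {lab: np.flatnonzero(flat == lab)[0] for lab in keep}
    ordered = sorted(keep, key=lambda lab: first[lab])
    remap = np.zeros(n + 1, dtype=np.int32)
    for new_id, lab in enumerate(ordered, start=1):
        remap[lab] = new_id
    return remap[raw]


def roi_areas(labels: np.ndarray) -> RoiAreas:
    """Per-ROI pixel counts, their sum, and the image pixel count."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.ravel())
    per_roi = {int(i): int(c) for i, c in enumerate(counts) if i > 0 and c > 0}
    return RoiAreas(
        per_roi=per_roi,
        total=int(sum(per_roi.values())),
        image=int(labels.size),
    )
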