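"""Intensity standardization.

Three-class intensity clustering, then a two-pass contrast adjustment that
places the white-matter histogram mode at 80% of the 16-bit range, squares
the intensities to separate the tissue peaks, and rescales again.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volumes import LabelMap, ValidationError, Volume, gaussian_smooth

__all__ = [
    "TissueMap",
    "segment_tissues",
    "white_matter_mode",
    "normalize_intensity",
    "head_mask",
]

SIXTEEN_BIT_MAX = 65535.0
WM_TARGET = 0.8 * SIXTEEN_BIT_MAX  # 52428
N_BINS = 256


@dataclass
class TissueMap:
    """3-class tissue labels: 0 bg/out-of-mask, 1 CSF-like, 2 gray-like, 3 white-like,
    ordered by increasing class mean intensity."""

    labels: np.ndarray

    def class_mask(self, k: int) -> np.ndarray:
        return self.labels == k


def head_mask(v: Volume, sigma_mm: float = 1.0) -> LabelMap:
    """Rough foreground mask: Otsu threshold on the smoothed image, holes filled.

    Phantoms carry an implicit head support; for real data users should
    supply a proper brain mask instead.
    """
    sm = gaussian_smooth(v, sigma_mm).data
    thr = threshold_otsu(sm)
    mask = ndimage.binary_fill_holes(sm > 0.5 * thr)
    return LabelMap(mask.astype(np.int16), v.spacing, v.origin)


def _kmeans_1d(values: np.ndarray, k: int = 3, max_iter: int = 100):
    """Deterministic 1-D k-means initialized at the 25/50/75th percentiles."""
    centers = np.percentile(values, [25.0, 50.0, 75.0]).astype(float)
    centers = np.sort(centers)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = values[assign == j]
            if sel.size:
                new[j] = sel.mean()
        new = np.sort(new)
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    return assign, centers


def segment_tissues(v: Volume, mask: LabelMap | None = None) -> TissueMap:
    """3-class 1-D k-means over in-mask intensities, classes ordered by mean.

    Without a mask, the nonzero support of the image is used.
    """
    if mask is not None:
        sel = mask.labels > 0
    else:
        sel = v.data != 0
    vals = v.data[sel]
    if np.unique(vals).size < 3:
        raise ValidationError("need >= 3 distinct intensity values for tissue clustering")
    assign, _ = _kmeans_1d(vals.astype(float))
    labels = np.zeros(v.shape, dtype=np.int16)
    labels[sel] = assign.astype(np.int16) + 1  # classes 1..3, ordered by mean
    return TissueMap(labels)


def white_matter_mode(v: Volume, t: TissueMap) -> float:
    """Mode of class-3 (white-like) intensities: midpoint of the tallest bin
    of a 256-bin histogram over the class-3 intensity range.

    The range is clipped to the 0.5-99.5 intensity percentiles so a handful
    of outlier voxels cannot stretch the bins (the estimate stays exactly
    scale-equivariant: percentiles, bin edges and the mode all scale with the
    image).
    """
    vals = v.data[t.class_mask(3)]
    if vals.size == 0:
        raise ValidationError("white-like tissue class is empty")
    lo, hi = (float(x) for x in np.percentile(vals, [0.5, 99.5]))
    if lo == hi:
        return lo
    counts, edges = np.histogram(np.clip(vals, lo, hi), bins=N_BINS, range=(lo, hi))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def normalize_intensity(v: Volume, mask: LabelMap | None = None) -> Volume:
    """Two-pass white-matter-mode standardization.

    1. cluster tissues, scale so the white-matter mode sits at 0.8 * 65535;
    2. square the intensities (peak separation) and rescale so the
       re-estimated white-matter mode is again at 0.8 * 65535.

    Negative intensities are clipped to 0 first so the overall transform is
    monotone non-decreasing; output is clamped to [0, 65535].
    """
    data = np.maximum(v.data, 0.0)
    work = v.like(data)
    tissues = segment_tissues(work, mask)

    mode1 = white_matter_mode(work, tissues)
    if mode1 <= 0:
        raise ValidationError("white-matter mode is non-positive; cannot rescale")
    scaled = data * (WM_TARGET / mode1)

    squared = scaled**2
    # squaring is monotone on [0, inf): tissue class membership is unchanged
    mode2 = white_matter_mode(work.like(squared), tissues)
    if mode2 <= 0:
        raise ValidationError("post-squaring white-matter mode is non-positive")
    out = squared * (WM_TARGET / mode2)
    return v.like(np.clip(out, 0.0, SIXTEEN_BIT_MAX))
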