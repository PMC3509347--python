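"""Locally similarity-weighted multi-atlas label voting.

Each warped atlas votes at each voxel with weight
``(eps + sum of squared intensity differences over a (2r+1)^3 patch)^(-beta)``;
a structure is assigned where its weighted vote fraction reaches 0.5. Voting
is independent per voxel and per hemisphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelMap, ValidationError, Volume

__all__ = ["WarpedAtlas", "VoteMap", "weight_map", "weighted_vote", "fuse_structures"]

log = logging.getLogger(__name__)

PATCH_RADIUS = 2
BETA = 2.0
EPS = 1e-6


@dataclass
class WarpedAtlas:
    """An atlas image + labels warped onto the test subject's (ROI) grid."""

    id: str
    image: Volume
    labels: LabelMap

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValidationError(f"atlas {self.id}: image/label grids differ")


@dataclass
class VoteMap:
    """Weighted vote fraction per voxel for one structure, in [0, 1]."""

    fraction: Volume
    structure_label: int


def _patch_ssd(test: np.ndarray, atlas: np.ndarray, radius: int) -> np.ndarray:
    """Sum of squared differences over the (2r+1)^3 cube clipped at borders."""
    d2 = (test - atlas) ** 2
    w = np.ones(2 * radius + 1)
    out = d2
    for axis in range(3):
        out = ndimage.correlate1d(out, w, axis=axis, mode="constant", cval=0.0)
    return out


def weight_map(test: Volume, atlas: WarpedAtlas, patch_radius: int = PATCH_RADIUS,
               beta: float = BETA, eps: float = EPS) -> Volume:
    """Inverse patch-distance similarity weight, finite and > 0 everywhere."""
    if test.shape != atlas.image.shape:
        raise ValidationError(
            f"grid mismatch: test {test.shape} vs atlas {atlas.image.shape}"
        )
    ssd = _patch_ssd(test.data, atlas.image.data, patch_radius)
    return test.like((eps + ssd) ** (-beta))


def weighted_vote(test: Volume, atlases: list[WarpedAtlas], structure_label: int,
                  patch_radius: int = PATCH_RADIUS, beta: float = BETA,
                  eps: float = EPS) -> tuple[LabelMap, VoteMap]:
    """Similarity-weighted voting for one structure.

    vote(x) = sum_i w_i(x) * [labels_i(x) == structure] / sum_i w_i(x);
    the structure is assigned where vote >= 0.5 (inclusive threshold).
    """
    if len(atlases) < 2:
        raise ValidationError("weighted voting needs >= 2 atlases")
    num = np.zeros(test.shape)
    den = np.zeros(test.shape)
    for atlas in atlases:
        w = weight_map(test, atlas, patch_radius, beta, eps).data
        num += w * (atlas.labels.labels == structure_label)
        den += w
    if not (den > 0).all():
        raise RuntimeError("zero total vote weight encountered")  # impossible given eps
    frac = num / den
    seg = np.where(frac >= 0.5, structure_label, 0).astype(np.int16)
    return (
        LabelMap(seg, test.spacing, test.origin),
        VoteMap(test.like(frac), structure_label),
    )


def fuse_structures(segs_votes: dict) -> LabelMap:
    """Merge independent per-hemisphere segmentations into one label map.

    ``segs_votes`` maps structure label -> (LabelMap on the full grid, VoteMap
    on the full grid). Voxels claimed by both hemispheres go to the higher
    vote fraction, ties to the left (label 1) structure.
    """
    labels = sorted(segs_votes)
    ref_seg, _ = segs_votes[labels[0]]
    out = np.zeros(ref_seg.shape, dtype=np.int16)
    best = np.full(ref_seg.shape, -1.0)
    for s in labels:  # ascending: on exact ties the lower (left) label wins
        seg, votes = segs_votes[s]
        claim = (seg.labels == s) & (votes.fraction.data > best)
        n_over = int(((out != 0) & claim).sum())
        if n_over:
            log.info("hemisphere overlap: %d voxels reassigned to label %d", n_over, s)
        out[claim] = s
        best[claim] = votes.fraction.data[claim]
    return LabelMap(out, ref_seg.spacing, ref_seg.origin)
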