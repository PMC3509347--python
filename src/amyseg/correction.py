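"""Boosted correction of systematic segmentation errors.

A working region is detected where initial segmentations historically
disagree with ground truth; inside it, a discrete AdaBoost ensemble of
decision stumps over appearance, contextual and spatial features classifies
each voxel as correctly labeled or mislabeled, and mislabeled voxels have
their binary structure label flipped. One model per structure/hemisphere.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .fusion import VoteMap
from .volumes import LabelMap, ValidationError, Volume

__all__ = [
    "FEATURE_NAMES",
    "Stump",
    "BoostModel",
    "Standardizer",
    "detect_bias_region",
    "extract_features",
    "train_adaboost",
    "correct_segmentation",
    "train_structure_corrector",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = (
    "intensity",
    "nbr_x_minus", "nbr_x_plus", "nbr_y_minus", "nbr_y_plus",
    "nbr_z_minus", "nbr_z_plus",
    "gradient_magnitude",
    "initial_label",
    "count_3cube",
    "count_5cube",
    "vote_fraction",
    "offset_x_mm", "offset_y_mm", "offset_z_mm",
)

SCHEMA_HASH = hashlib.sha256("|".join(FEATURE_NAMES).encode()).hexdigest()[:16]


@dataclass
class Stump:
    feature: int
    threshold: float
    polarity: int  # +1: predict +1 when x > threshold; -1: predict +1 when x <= threshold
    alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        above = X[:, self.feature] > self.threshold
        return np.where(above, self.polarity, -self.polarity).astype(float)


@dataclass
class Standardizer:
    """Per-feature zero-mean/unit-variance scaling fit on training data only.

    Zero-variance features are dropped (their indices are recorded)."""

    mean: np.ndarray = None
    std: np.ndarray = None
    kept: np.ndarray = None  # indices into the raw feature schema

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        self.kept = np.nonzero(self.std > 0)[0]
        dropped = [FEATURE_NAMES[i] for i in np.nonzero(self.std == 0)[0]]
        if dropped:
            log.info("dropping zero-variance features: %s", dropped)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.mean[self.kept]) / self.std[self.kept]


@dataclass
class BoostModel:
    stumps: list
    standardizer: Standardizer
    structure_label: int
    roi_box: tuple  # ((lo), (hi)) half-open, full-grid indices
    mask_offsets: np.ndarray  # (n, 3) voxel offsets of the working ROI, relative to roi_box lo
    rounds: int
    schema_hash: str = SCHEMA_HASH
    n_features: int = len(FEATURE_NAMES)

    def decision(self, X: np.ndarray) -> np.ndarray:
        score = np.zeros(X.shape[0])
        for s in self.stumps:
            score += s.alpha * s.predict(X)
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 = correctly labeled, -1 = mislabeled (sign of the weighted vote)."""
        return np.where(self.decision(X) >= 0, 1.0, -1.0)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "schema_hash": self.schema_hash,
            "n_features": self.n_features,
            "structure_label": self.structure_label,
            "rounds": self.rounds,
            "roi_box": [list(self.roi_box[0]), list(self.roi_box[1])],
            "mask_offsets": self.mask_offsets.tolist(),
            "standardizer": {
                "mean": self.standardizer.mean.tolist(),
                "std": self.standardizer.std.tolist(),
                "kept": self.standardizer.kept.tolist(),
            },
            "stumps": [
                {"feature": s.feature, "threshold": s.threshold,
                 "polarity": s.polarity, "alpha": s.alpha}
                for s in self.stumps
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "BoostModel":
        d = json.loads(text)
        std = Standardizer(
            mean=np.array(d["standardizer"]["mean"]),
            std=np.array(d["standardizer"]["std"]),
            kept=np.array(d["standardizer"]["kept"], dtype=int),
        )
        return cls(
            stumps=[Stump(**s) for s in d["stumps"]],
            standardizer=std,
            structure_label=d["structure_label"],
            roi_box=(tuple(d["roi_box"][0]), tuple(d["roi_box"][1])),
            mask_offsets=np.array(d["mask_offsets"], dtype=int).reshape(-1, 3),
            rounds=d["rounds"],
            schema_hash=d["schema_hash"],
            n_features=d["n_features"],
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "BoostModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Bias (working region) detection


def _ball(radius_vox: np.ndarray) -> np.ndarray:
    r = np.asarray(radius_vox, dtype=float)
    n = np.ceil(r).astype(int)
    grids = np.meshgrid(*[np.arange(-k, k + 1) for k in n], indexing="ij")
    q = sum((g / max(ri, 1e-12)) ** 2 for g, ri in zip(grids, r))
    return q <= 1.0 + 1e-12


def detect_bias_region(initial_segs: list, truths: list, dilation_mm: float = 2.0) -> LabelMap:
    """Union of (initial != truth) across subjects, dilated by a Euclidean
    ball of ``dilation_mm``. An empty union yields an empty mask (the
    corrector then degenerates to the identity)."""
    if len(initial_segs) != len(truths) or not initial_segs:
        raise ValidationError("need matched, nonempty lists of segmentations and truths")
    ref = initial_segs[0]
    union = np.zeros(ref.shape, dtype=bool)
    for seg, truth in zip(initial_segs, truths):
        if seg.shape != ref.shape or truth.shape != ref.shape:
            raise ValidationError("segmentations are not on a common grid")
        union |= seg.labels != truth.labels
    if not union.any():
        log.warning("no disagreement voxels: corrector will be the identity")
        return LabelMap(union.astype(np.int16), ref.spacing, ref.origin)
    if dilation_mm > 0:
        radius = dilation_mm / np.asarray(ref.spacing)
        union = ndimage.binary_dilation(union, structure=_ball(radius))
    return LabelMap(union.astype(np.int16), ref.spacing, ref.origin)


# ---------------------------------------------------------------------------
# Features


def _neighbor_shift(data: np.ndarray, axis: int, step: int) -> np.ndarray:
    """Shifted copy with edge replication (the 6-neighbour intensity maps)."""
    out = np.empty_like(data)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
        edge_dst, edge_src = slice(-1, None), slice(-1, None)
    else:
        src[axis] = slice(0, -1)
        dst[axis] = slice(1, None)
        edge_dst, edge_src = slice(0, 1), slice(0, 1)
    out[tuple(dst)] = data[tuple(src)]
    e_dst = [slice(None)] * 3
    e_dst[axis] = edge_dst
    e_src = [slice(None)] * 3
    e_src[axis] = edge_src
    out[tuple(e_dst)] = data[tuple(e_src)]
    return out


def _count_filter(binary: np.ndarray, size: int) -> np.ndarray:
    w = np.ones(size)
    out = binary.astype(float)
    for axis in range(3):
        out = ndimage.correlate1d(out, w, axis=axis, mode="constant", cval=0.0)
    return out


def extract_features(
    image: Volume,
    initial: LabelMap,
    votes: VoteMap,
    roi_box: tuple,
    structure_label: int,
    mask_offsets: np.ndarray,
) -> np.ndarray:
    """Raw (unstandardized) feature rows for the working-ROI voxels.

    Rows follow ``mask_offsets`` order (offsets are lexicographically sorted
    voxel indices relative to the ROI-box low corner). Columns follow
    :data:`FEATURE_NAMES`.
    """
    if image.shape != initial.shape or image.shape != votes.fraction.shape:
        raise ValidationError("image/initial/votes grids differ")
    lo, hi = roi_box
    data = image.data
    binary = (initial.labels == structure_label).astype(float)

    grads = np.gradient(data)
    gradmag = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2)
    feats_full = [
        data,
        _neighbor_shift(data, 0, -1), _neighbor_shift(data, 0, +1),
        _neighbor_shift(data, 1, -1), _neighbor_shift(data, 1, +1),
        _neighbor_shift(data, 2, -1), _neighbor_shift(data, 2, +1),
        gradmag,
        binary,
        _count_filter(binary, 3),
        _count_filter(binary, 5),
        votes.fraction.data,
    ]
    ii = mask_offsets[:, 0] + lo[0]
    jj = mask_offsets[:, 1] + lo[1]
    kk = mask_offsets[:, 2] + lo[2]
    cols = [f[ii, jj, kk] for f in feats_full]

    center = (np.asarray(lo) + np.asarray(hi) - 1) / 2.0
    sp = np.asarray(image.spacing)
    for a in range(3):
        cols.append((mask_offsets[:, a] + lo[a] - center[a]) * sp[a])

    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValidationError(
            f"non-finite feature {FEATURE_NAMES[bad[1]]} at row {bad[0]}"
        )
    return X


def mask_to_offsets(mask: LabelMap, roi_box: tuple) -> np.ndarray:
    """Working-ROI voxels inside the box as lexicographically sorted offsets."""
    lo, hi = roi_box
    sub = mask.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] > 0
    return np.argwhere(sub)  # argwhere is already lexicographic


# ---------------------------------------------------------------------------
# AdaBoost


def _train_stumps(X: np.ndarray, y: np.ndarray, w0: np.ndarray, T: int):
    """Discrete AdaBoost with exhaustive decision stumps.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each feature (plus a below-all threshold); the weighted error
    at every split is computed with cumulative sums over a precomputed sort.
    Returns (stumps, epsilons).
    """
    n, f = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    w = w0.copy()
    stumps: list[Stump] = []
    epsilons: list[float] = []

    for _ in range(T):
        best = None  # (eps, feature, threshold, polarity)
        for j in range(f):
            o = order[:, j]
            wy = (w * y)[o]
            cum = np.concatenate([[0.0], np.cumsum(wy)])  # cum[i] = sum of w*y for first i sorted
            total_pos = float(w[y > 0].sum())
            # split after position i (first i samples are <= threshold):
            # polarity +1 (predict +1 above): err = sum_{<=thr, y=+1} w + sum_{>thr, y=-1} w
            # sum_{<=i, y=+1} w = (cum_i + cumw_i)/2 where cumw = cumsum of w
            cw = np.concatenate([[0.0], np.cumsum(w[o])])
            pos_below = (cum + cw) / 2.0
            # neg_above = total_neg - neg_below, with neg_below = (cw - cum)/2
            neg_above = (float(w.sum()) - total_pos) - (cw - cum) / 2.0
            err_plus = pos_below + neg_above
            err_minus = float(w.sum()) - err_plus
            # valid split positions: between distinct consecutive values, plus ends
            vals = Xs[:, j]
            distinct = np.concatenate([[True], vals[1:] != vals[:-1], [True]])
            idxs = np.nonzero(distinct)[0]
            for errs, pol in ((err_plus, 1), (err_minus, -1)):
                e = errs[idxs]
                k = int(np.argmin(e))
                if best is None or e[k] < best[0] - 1e-15:
                    pos = idxs[k]
                    if pos == 0:
                        thr = vals[0] - 1.0
                    elif pos == n:
                        thr = vals[-1] + 1.0
                    else:
                        thr = 0.5 * (vals[pos - 1] + vals[pos])
                    best = (float(e[k]), j, float(thr), pol)
        eps, j, thr, pol = best
        eps = max(eps / float(w.sum()), 0.0)  # cumsum round-off can go barely negative
        if eps >= 0.5 - 1e-9:
            break
        eps_c = max(eps, 1e-12)
        alpha = 0.5 * np.log((1.0 - eps_c) / eps_c)
        stump = Stump(feature=j, threshold=thr, polarity=pol, alpha=float(alpha))
        stumps.append(stump)
        epsilons.append(eps)
        if eps <= 1e-12:
            break
        pred = stump.predict(X)
        w = w * np.exp(-alpha * y * pred)
        w = w / w.sum()
    return stumps, epsilons


def train_adaboost(X: np.ndarray, y: np.ndarray, T: int = 100,
                   class_balanced: bool = False):
    """Classic discrete AdaBoost over decision stumps.

    ``y`` in {+1, -1}. Initial weights are uniform (1/n), or, with
    ``class_balanced``, scaled so each class sums to 1/2. Training halts when
    the best achievable weighted error reaches 0.5 (alpha would be 0) or hits
    exactly 0. Returns ``(stumps, epsilons)``; the per-round weighted errors
    satisfy the exponential bound
    ``weighted training error <= prod_t 2 sqrt(eps_t (1 - eps_t))``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not ((y == 1) | (y == -1)).all():
        raise ValidationError("labels must be +1/-1")
    if (y == 1).all() or (y == -1).all():
        raise ValidationError("both classes must be present")
    n = len(y)
    if class_balanced:
        w0 = np.where(y > 0, 0.5 / max((y > 0).sum(), 1), 0.5 / max((y < 0).sum(), 1))
    else:
        w0 = np.full(n, 1.0 / n)
    return _train_stumps(X, y, w0, T)


# ---------------------------------------------------------------------------
# End-to-end corrector


def train_structure_corrector(
    images: list,
    initials: list,
    votes: list,
    truths: list,
    roi_box: tuple,
    structure_label: int,
    rounds: int = 100,
    dilation_mm: float = 2.0,
) -> BoostModel:
    """Train one per-structure corrector from cross-validated initial
    segmentations of training subjects (all on a common grid)."""
    bin_inits = [
        LabelMap((s.labels == structure_label).astype(np.int16), s.spacing, s.origin)
        for s in initials
    ]
    bin_truths = [
        LabelMap((t.labels == structure_label).astype(np.int16), t.spacing, t.origin)
        for t in truths
    ]
    mask = detect_bias_region(bin_inits, bin_truths, dilation_mm)
    offsets = mask_to_offsets(mask, roi_box)
    std = Standardizer()
    if offsets.shape[0] == 0:
        std.fit(np.zeros((1, len(FEATURE_NAMES))))
        return BoostModel([], std, structure_label, roi_box, offsets.reshape(0, 3), rounds)

    rows, targets = [], []
    lo = roi_box[0]
    ii, jj, kk = (offsets[:, a] + lo[a] for a in range(3))
    for img, init, vote, truth in zip(images, initials, votes, truths):
        rows.append(extract_features(img, init, vote, roi_box, structure_label, offsets))
        correct = (init.labels == structure_label) == (truth.labels == structure_label)
        targets.append(np.where(correct[ii, jj, kk], 1.0, -1.0))
    X = np.vstack(rows)
    y = np.concatenate(targets)
    std.fit(X)
    if (y == 1).all() or (y == -1).all():
        # inside the dilated region everything is (un)mislabeled uniformly:
        # nothing learnable, fall back to identity
        log.warning("single-class corrector training set; using identity corrector")
        return BoostModel([], std, structure_label, roi_box, offsets, rounds)
    stumps, _ = train_adaboost(std.transform(X), y, T=rounds, class_balanced=False)
    return BoostModel(stumps, std, structure_label, roi_box, offsets, rounds)


def correct_segmentation(initial: LabelMap, model: BoostModel, image: Volume,
                         votes: VoteMap) -> LabelMap:
    """Flip the binary structure label of voxels the model calls mislabeled.

    Only working-ROI voxels may change; everything else is passed through.
    """
    if votes.structure_label != model.structure_label:
        raise ValidationError("vote map structure does not match model structure")
    out = initial.copy()
    if model.mask_offsets.shape[0] == 0 or not model.stumps:
        return out
    X = extract_features(image, initial, votes, model.roi_box,
                         model.structure_label, model.mask_offsets)
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature schema mismatch: got {X.shape[1]} features, model has {model.n_features}"
        )
    pred = model.predict(model.standardizer.transform(X))
    flip = pred < 0
    lo = model.roi_box[0]
    ii = model.mask_offsets[flip, 0] + lo[0]
    jj = model.mask_offsets[flip, 1] + lo[1]
    kk = model.mask_offsets[flip, 2] + lo[2]
    s = model.structure_label
    cur = out.labels[ii, jj, kk]
    out.labels[ii, jj, kk] = np.where(cur == s, 0, s).astype(np.int16)
    return out
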