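"""Seeded synthetic cohort generator.

Produces "training" (atlas) and "test" subjects as smooth diffeomorphic
deformations of one shared multi-tissue ellipsoid head, each with a bias
field, additive Gaussian noise, and a ground-truth label map carrying two
mirror-placed lateralized target structures (label 1 left, label 2 right).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .register import compose
from .volumes import (
    DeformationField,
    LabelMap,
    ValidationError,
    Volume,
    apply_deformation,
    min_interior_jacobian,
    write_volume,
)

__all__ = [
    "PhantomParams",
    "SubjectCase",
    "make_base_phantom",
    "random_diffeomorphism",
    "simulate_subject",
    "simulate_cohort",
    "save_cohort",
    "load_cohort",
]

log = logging.getLogger(__name__)

MAX_STEP = 0.4  # max per-step displacement (voxels) in scaling-and-squaring
MIN_SQUARINGS = 6


@dataclass(frozen=True)
class PhantomParams:
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: tuple[float, float, float, float] = (0.0, 40.0, 100.0, 160.0)  # bg/CSF/gray/white
    structure_contrast: float = 30.0  # offset of target structures from gray
    warp_amplitude: float = 3.0  # max displacement, voxels
    warp_smoothness: float = 5.0  # sigma of random velocity smoothing, voxels
    bias_strength: float = 0.05
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in np.broadcast_to(self.shape, (3,)))
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", tuple(float(s) for s in np.broadcast_to(self.spacing, (3,))))
        if min(shape) < 16:
            raise ValidationError(f"phantom shape must be >= 16 per axis, got {shape}")
        if self.warp_amplitude < 0:
            raise ValidationError("warp_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SubjectCase:
    id: str
    image: Volume
    truth: LabelMap

    def __post_init__(self):
        if self.image.shape != self.truth.shape:
            raise ValidationError("image and truth grids differ")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def make_base_phantom(p: PhantomParams) -> SubjectCase:
    """Deterministic (seed-independent), noiseless base subject.

    Concentric head/CSF/gray/white ellipsoid shells plus two lateralized
    target ellipsoids of intensity gray + structure_contrast, mirror
    symmetric about the midsagittal (axis 0) plane.
    """
    shape = np.asarray(p.shape, dtype=float)
    center = (shape - 1) / 2.0
    # anisotropic head: rotations must change the image, otherwise rigid
    # alignment of the cohort is ill-posed
    head_r = np.array([0.46, 0.40, 0.34]) * shape
    bg, csf, gray, white = p.tissue_means

    head = _ellipsoid(p.shape, center, head_r)
    gray_m = _ellipsoid(p.shape, center, 0.86 * head_r)
    white_m = _ellipsoid(p.shape, center, 0.58 * head_r)

    img = np.full(p.shape, float(bg))
    img[head] = csf
    img[gray_m] = gray
    img[white_m] = white

    # lateral target structures, mirror-placed about the axis-0 midplane
    off = np.array([0.42 * head_r[0], 0.0, -0.12 * head_r[2]])
    radii = np.maximum(0.16 * shape * 0.44, 2.0)
    c_left = center - np.array([off[0], 0, 0]) + np.array([0, off[1], off[2]])
    c_right = center + np.array([off[0], 0, 0]) + np.array([0, off[1], off[2]])
    left = _ellipsoid(p.shape, c_left, radii)
    right = _ellipsoid(p.shape, c_right, radii)
    if not (left & head).sum() == left.sum() or not (right & head).sum() == right.sum():
        raise ValidationError("target structures fall outside the head")

    img[left] = gray + p.structure_contrast
    img[right] = gray + p.structure_contrast
    labels = np.zeros(p.shape, dtype=np.int16)
    labels[left] = 1
    labels[right] = 2

    return SubjectCase(
        id="base",
        image=Volume(img, p.spacing),
        truth=LabelMap(labels, p.spacing),
    )


def random_diffeomorphism(p: PhantomParams, seed: int) -> DeformationField:
    """Random diffeomorphic deformation by velocity exponentiation.

    A Gaussian-smoothed random velocity field scaled to max norm
    ``warp_amplitude`` is exponentiated by scaling-and-squaring with enough
    squarings that each step moves <= 0.4 voxel, guaranteeing a positive
    Jacobian determinant by construction. Bit-reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((3, *p.shape))
    if p.warp_amplitude == 0:
        return DeformationField.zero(p.shape, p.spacing)
    v = np.stack([ndimage.gaussian_filter(c, p.warp_smoothness, mode="nearest") for c in v])
    # taper to zero at the grid boundary: keeps the interior max the global
    # max (edge-replicated smoothing inflates corner values) and keeps warps
    # contained inside the field of view
    width = max(2.0 * p.warp_smoothness, 1.0)
    for axis, n in enumerate(p.shape):
        t = np.arange(n, dtype=float)
        w = np.clip(np.minimum(t, n - 1 - t) / width, 0.0, 1.0)
        v *= w.reshape([1] + [n if a == axis else 1 for a in range(3)])
    norm = np.sqrt((v**2).sum(axis=0)).max()
    v *= p.warp_amplitude / max(norm, 1e-30)

    n_sq = max(MIN_SQUARINGS, int(np.ceil(np.log2(max(p.warp_amplitude / MAX_STEP, 1.0)))))
    d = DeformationField(v / (2**n_sq), p.spacing)
    for _ in range(n_sq):
        d = compose(d, d)
    if min_interior_jacobian(d) <= 0:
        raise RuntimeError("random diffeomorphism produced non-positive Jacobian")
    return d


def _bias_field(p: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive low-order polynomial gain with mean 1."""
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in p.shape], indexing="ij"
    )
    coef = rng.uniform(-1.0, 1.0, size=9)
    g = (
        coef[0] * grids[0] + coef[1] * grids[1] + coef[2] * grids[2]
        + coef[3] * grids[0] ** 2 + coef[4] * grids[1] ** 2 + coef[5] * grids[2] ** 2
        + coef[6] * grids[0] * grids[1] + coef[7] * grids[1] * grids[2]
        + coef[8] * grids[0] * grids[2]
    )
    gain = 1.0 + p.bias_strength * (g - g.mean())
    return np.maximum(gain, 0.05)


def simulate_subject(base: SubjectCase, p: PhantomParams, seed: int,
                     subject_id: str | None = None) -> SubjectCase:
    """One synthetic subject: warp the base anatomy with a random
    diffeomorphism, multiply a bias gain, add Gaussian noise; the truth is
    transported with the same field (nearest-neighbour)."""
    sid = subject_id or f"subj_{seed}"
    for attempt in range(5):
        sub_seed = seed if attempt == 0 else hash((seed, attempt)) % (2**31)
        d = random_diffeomorphism(p, sub_seed)
        truth = apply_deformation(base.truth, d, "nearest")
        if (truth.labels == 1).any() and (truth.labels == 2).any():
            break
        log.warning("subject %s: structure warped to empty, retrying (attempt %d)",
                    sid, attempt + 1)
    else:
        raise RuntimeError(f"subject {sid}: structures empty after retries")

    img = apply_deformation(base.image, d, "trilinear")
    rng = np.random.default_rng([sub_seed, 1])
    data = img.data
    if p.bias_strength > 0:
        data = data * _bias_field(p, rng)
    if p.noise_sd > 0:
        data = data + rng.normal(0.0, p.noise_sd, size=p.shape)
    return SubjectCase(id=sid, image=Volume(data, p.spacing), truth=truth)


def _params_hash(p: PhantomParams) -> str:
    return hashlib.sha256(json.dumps(asdict(p), sort_keys=True).encode()).hexdigest()[:16]


def simulate_cohort(n_train: int, n_test: int, p: PhantomParams, seed: int):
    """Generate disjoint-seeded train/test cohorts from one base phantom.

    Returns ``(train, test)`` lists of :class:`SubjectCase`. Fully
    reproducible from ``(p, seed)``.
    """
    if n_train < 2:
        raise ValidationError("n_train must be >= 2 (fusion needs >= 2 atlases)")
    base = make_base_phantom(p)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_train + n_test)]
    train = [
        simulate_subject(base, p, seeds[i], subject_id=f"train_{i:02d}")
        for i in range(n_train)
    ]
    test = [
        simulate_subject(base, p, seeds[n_train + j], subject_id=f"test_{j:02d}")
        for j in range(n_test)
    ]
    return train, test


def save_cohort(train, test, p: PhantomParams, seed: int, out_dir) -> Path:
    """Write cohort NIfTIs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for group, cases in (("train", train), ("test", test)):
        for c in cases:
            write_volume(c.image, out / f"{c.id}_image.nii.gz")
            write_volume(c.truth, out / f"{c.id}_labels.nii.gz")
            entries.append({"id": c.id, "group": group,
                            "image": f"{c.id}_image.nii.gz",
                            "labels": f"{c.id}_labels.nii.gz"})
    manifest = {
        "seed": seed,
        "params": asdict(p),
        "params_hash": _params_hash(p),
        "subjects": entries,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_cohort(cohort_dir):
    """Read a saved cohort back as ``(train, test)`` lists of SubjectCase."""
    from .volumes import read_labels, read_volume

    d = Path(cohort_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"cohort manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    train, test = [], []
    for e in manifest["subjects"]:
        case = SubjectCase(
            id=e["id"],
            image=read_volume(d / e["image"]),
            truth=read_labels(d / e["labels"]),
        )
        (train if e["group"] == "train" else test).append(case)
    return train, test
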