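"""Core 3D image containers, NIfTI I/O, resampling, smoothing and warping.

Conventions used throughout the package:

* voxel indices are 0-based; world coordinate = ``origin + index * spacing``
  (canonical axis order, no orientation-code handling);
* displacement fields are stored in **voxel units of the fixed grid**;
* ROI boxes are half-open ``[lo, hi)`` in voxel indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMap",
    "DeformationField",
    "RigidTransform",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_field",
    "read_field",
    "resample",
    "gaussian_smooth",
    "apply_deformation",
    "jacobian_determinant",
]

_LABEL_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray
        3D float array.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")
        if np.isnan(self.data).any():
            raise ValidationError("volume data contains NaN")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume with the same geometry and the given data."""
        return Volume(np.asarray(data, dtype=np.float64), self.spacing, self.origin)


@dataclass
class LabelMap:
    """Integer label grid aligned with a :class:`Volume`.

    Label semantics: 0 = background, 1 = left structure, 2 = right structure.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            bad = np.abs(self.labels - rounded) > _LABEL_TOL
            if bad.any():
                offending = np.unique(self.labels[bad])[:10]
                raise ValidationError(
                    f"non-integral label values beyond tolerance {_LABEL_TOL}: {offending}"
                )
            if np.abs(self.labels - rounded).max() > 0:
                warnings.warn("label values rounded to nearest integer", stacklevel=2)
            self.labels = rounded.astype(np.int16)
        else:
            self.labels = self.labels.astype(np.int16)
        if self.labels.ndim != 3:
            raise ValidationError(f"label data must be 3D, got shape {self.labels.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "LabelMap":
        return replace(self, labels=self.labels.copy())

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label

    def volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume_mm3


@dataclass
class DeformationField:
    """Per-voxel displacement on a fixed grid, in voxel units.

    ``disp`` has shape ``(3,) + grid_shape``; sampling semantics are
    ``output(x) = input(x + disp[:, x])``.
    """

    disp: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValidationError(
                f"displacement must have shape (3, nx, ny, nz), got {self.disp.shape}"
            )
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[1:]

    @classmethod
    def zero(cls, shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> "DeformationField":
        return cls(np.zeros((3, *shape)), spacing, origin)

    def copy(self) -> "DeformationField":
        return replace(self, disp=self.disp.copy())

    def max_norm(self) -> float:
        return float(np.sqrt((self.disp**2).sum(axis=0)).max())


@dataclass
class RigidTransform:
    """6-dof rigid-body transform: fixed world point ``p`` maps to the moving
    world point ``R @ (p - center) + center + translation``."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Euler angles, radians (x, y, z)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self):
        self.rotation = _as_triple(self.rotation, "rotation")
        self.translation = _as_triple(self.translation, "translation")
        self.center = _as_triple(self.center, "center")

    @property
    def matrix(self) -> np.ndarray:
        ax, ay, az = self.rotation
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def apply_points(self, pts: np.ndarray, inverse: bool = False) -> np.ndarray:
        """Map world points ``pts`` (..., 3). ``inverse=True`` applies the exact
        inverse mapping."""
        r = self.matrix
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        p = np.asarray(pts, dtype=float)
        if inverse:
            return (p - c - t) @ r + c  # (p - c - t) @ R == R.T @ (p - c - t)
        return (p - c) @ r.T + c + t


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return np.asarray(data), spacing, origin


def read_volume(path) -> Volume:
    """Read a single-file NIfTI-1 image as a float :class:`Volume`."""
    data, spacing, origin = _load_nifti(path)
    return Volume(data.astype(np.float64), spacing, origin)


def read_labels(path) -> LabelMap:
    """Read a NIfTI-1 image as a :class:`LabelMap`.

    Values within 1e-6 of an integer are rounded (with a warning); anything
    further off raises :class:`ValidationError`.
    """
    data, spacing, origin = _load_nifti(path)
    return LabelMap(data, spacing, origin)


def write_volume(v, path) -> None:
    """Write a :class:`Volume` (float32) or :class:`LabelMap` (int16) to NIfTI-1."""
    if isinstance(v, LabelMap):
        data = v.labels.astype(np.int16)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling / smoothing


def write_field(d: DeformationField, path) -> None:
    """Store a displacement field as a 4D NIfTI with 3 components (voxel units)."""
    data = np.moveaxis(d.disp, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(d.spacing, d.origin))
    nib.save(img, str(path))


def read_field(path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValidationError(f"{path}: expected (nx, ny, nz, 3) field, got {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DeformationField(np.moveaxis(data, -1, 0).astype(np.float64), spacing, origin)


def resample(v: Volume, factor: int, mode: str = "subsample", target_shape=None) -> Volume:
    """Integer-factor subsampling by block averaging, or trilinear restore.

    ``subsample``: output shape = ceil(shape / factor), spacing * factor; each
    output voxel is the mean of its (up to) ``factor**3`` source block (edge
    blocks are padded by edge replication).
    ``restore``: trilinear interpolation back to ``target_shape`` on the
    original (spacing / factor) grid.
    """
    if int(factor) != factor or factor < 1:
        raise ValidationError(f"resample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if mode == "subsample":
        if factor == 1:
            return v.copy()
        data = v.data
        pad = [(0, (-s) % factor) for s in data.shape]
        data = np.pad(data, pad, mode="edge")
        nx, ny, nz = (s // factor for s in data.shape)
        f = factor
        blocks = data.reshape(nx, f, ny, f, nz, f)
        out = blocks.mean(axis=(1, 3, 5))
        return Volume(out, tuple(s * factor for s in v.spacing), v.origin)
    if mode == "restore":
        if target_shape is None:
            raise ValidationError("restore mode requires target_shape")
        if factor == 1 and tuple(target_shape) == v.shape:
            return v.copy()
        # coarse voxel j covers fine voxels [j*f, j*f + f); its center sits at
        # fine index j*f + (f-1)/2, hence the inverse mapping below.
        coords = np.meshgrid(
            *[(np.arange(n) - (factor - 1) / 2.0) / factor for n in target_shape],
            indexing="ij",
        )
        out = ndimage.map_coordinates(v.data, np.stack(coords), order=1, mode="nearest")
        return Volume(out, tuple(s / factor for s in v.spacing), v.origin)
    raise ValidationError(f"unknown resample mode {mode!r}")


def gaussian_smooth(v: Volume, sigma_mm) -> Volume:
    """Separable Gaussian smoothing; sigma given in mm per axis, converted to
    voxels via the spacing. Boundaries use edge replication."""
    sigma = np.broadcast_to(np.asarray(sigma_mm, dtype=float), (3,))
    if (sigma < 0).any():
        raise ValidationError(f"sigma must be non-negative, got {sigma}")
    sigma_vox = sigma / np.asarray(v.spacing)
    if (sigma_vox == 0).all():
        return v.copy()
    out = ndimage.gaussian_filter(v.data, sigma=sigma_vox, mode="nearest")
    return v.like(out)


# ---------------------------------------------------------------------------
# Deformation


def _identity_coords(shape) -> np.ndarray:
    return np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))


def apply_deformation(v, d: DeformationField, interp: str = "trilinear"):
    """Warp a Volume or LabelMap: ``output(x) = input(x + disp(x))``.

    LabelMaps always use nearest-neighbour sampling (a trilinear request is
    overridden with a warning). Out-of-bounds samples take 0 for labels and
    the edge value for volumes.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    is_labels = isinstance(v, LabelMap)
    if is_labels and interp != "nearest":
        warnings.warn("LabelMap warping forces nearest-neighbour interpolation", stacklevel=2)
        interp = "nearest"
    if v.shape != d.shape:
        raise ValidationError(f"grid shape mismatch: image {v.shape} vs field {d.shape}")
    coords = _identity_coords(d.shape) + d.disp
    if is_labels:
        out = ndimage.map_coordinates(
            v.labels, coords, order=0, mode="constant", cval=0
        )
        return LabelMap(out, v.spacing, v.origin)
    out = ndimage.map_coordinates(v.data, coords, order=1, mode="nearest")
    return Volume(out, v.spacing, v.origin)


def jacobian_determinant(d: DeformationField) -> Volume:
    """Determinant of the Jacobian of ``x -> x + disp(x)``.

    Central differences at interior voxels, one-sided at the boundary
    (``numpy.gradient`` semantics). Requires >= 3 voxels per axis.
    """
    if min(d.shape) < 3:
        raise ValidationError(f"grid must be >= 3 voxels per axis, got {d.shape}")
    j = np.empty((3, 3, *d.shape))
    for i in range(3):
        grads = np.gradient(d.disp[i], axis=(0, 1, 2))
        for a in range(3):
            j[i, a] = grads[a] + (1.0 if i == a else 0.0)
    det = (
        j[0, 0] * (j[1, 1] * j[2, 2] - j[1, 2] * j[2, 1])
        - j[0, 1] * (j[1, 0] * j[2, 2] - j[1, 2] * j[2, 0])
        + j[0, 2] * (j[1, 0] * j[2, 1] - j[1, 1] * j[2, 0])
    )
    return Volume(det, d.spacing, d.origin)


def min_interior_jacobian(d: DeformationField) -> float:
    """Minimum Jacobian determinant over interior voxels (diffeomorphism check)."""
    det = jacobian_determinant(d).data
    return float(det[1:-1, 1:-1, 1:-1].min())
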