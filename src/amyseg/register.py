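"""Rigid and multi-resolution diffeomorphic registration.

The deformable stage is a greedy demons-style scheme with a per-iteration
step-size cap and field smoothing, run over a coarse-to-fine schedule.
Updates are only accepted when they reduce the mean squared difference and
keep the Jacobian determinant positive, so every emitted field is a
discretely-checked diffeomorphism and the metric trace is non-increasing.
No randomness is used anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .volumes import (
    DeformationField,
    LabelMap,
    ValidationError,
    Volume,
    _identity_coords,
    min_interior_jacobian,
    resample,
    RigidTransform,
)

__all__ = [
    "Schedule",
    "RegResult",
    "rigid_register",
    "apply_rigid",
    "diffeo_register",
    "compose",
    "invert_deformation",
]

DEFAULT_LEVELS = ((4, 80), (2, 80), (1, 30))


@dataclass(frozen=True)
class Schedule:
    """Coarse-to-fine schedule: ordered (subsample_factor, max_iterations)."""

    levels: tuple = DEFAULT_LEVELS

    def __post_init__(self):
        levels = tuple((int(f), int(it)) for f, it in self.levels)
        object.__setattr__(self, "levels", levels)
        factors = [f for f, _ in levels]
        if any(f2 > f1 for f1, f2 in zip(factors, factors[1:])):
            raise ValidationError(f"subsample factors must be non-increasing: {factors}")
        if factors[-1] != 1:
            raise ValidationError("last schedule level must be full resolution (factor 1)")
        if any(it < 1 for _, it in levels):
            raise ValidationError("iteration counts must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "Schedule":
        """Parse e.g. ``"4x80,2x80,1x30"``."""
        levels = []
        for part in text.split(","):
            f, it = part.lower().split("x")
            levels.append((int(f), int(it)))
        return cls(tuple(levels))


@dataclass
class RegResult:
    """Registration output.

    ``metric_trace`` concatenates per-iteration MSD values of all levels;
    ``level_boundaries[i]`` indexes the initial metric of level ``i``. The
    metric is evaluated on each level's (subsampled) grid, so values are
    comparable — and non-increasing by construction — within a level.
    """

    field: DeformationField
    metric_trace: list = dc_field(default_factory=list)
    level_boundaries: list = dc_field(default_factory=list)
    converged: bool = False

    def level_traces(self) -> list:
        bounds = list(self.level_boundaries) + [len(self.metric_trace)]
        return [self.metric_trace[a:b] for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# Rigid registration


def _sample_rigid(moving: Volume, fixed: Volume, t: RigidTransform, inverse=False) -> np.ndarray:
    """Resample moving onto the fixed grid through the rigid transform."""
    idx = _identity_coords(fixed.shape)
    world = idx * np.asarray(fixed.spacing).reshape(3, 1, 1, 1) + np.asarray(
        fixed.origin
    ).reshape(3, 1, 1, 1)
    pts = t.apply_points(np.moveaxis(world, 0, -1), inverse=inverse)
    vox = (pts - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    return ndimage.map_coordinates(
        moving.data, np.moveaxis(vox, -1, 0), order=1, mode="nearest"
    )


def apply_rigid(moving, t: RigidTransform, reference: Volume, inverse: bool = False,
                interp: str = "trilinear"):
    """Resample ``moving`` (Volume or LabelMap) onto ``reference``'s grid.

    ``inverse=True`` applies the exact inverse transform (used to map results
    back to native space without extracting inverse Euler angles).
    """
    idx = _identity_coords(reference.shape)
    world = idx * np.asarray(reference.spacing).reshape(3, 1, 1, 1) + np.asarray(
        reference.origin
    ).reshape(3, 1, 1, 1)
    pts = t.apply_points(np.moveaxis(world, 0, -1), inverse=inverse)
    vox = np.moveaxis(
        (pts - np.asarray(moving.origin)) / np.asarray(moving.spacing), -1, 0
    )
    if isinstance(moving, LabelMap):
        out = ndimage.map_coordinates(moving.labels, vox, order=0, mode="constant", cval=0)
        return LabelMap(out, reference.spacing, reference.origin)
    out = ndimage.map_coordinates(moving.data, vox, order=1, mode="nearest")
    return Volume(out, reference.spacing, reference.origin)


def _centroid_world(v: Volume) -> np.ndarray:
    w = v.data - v.data.min()
    total = w.sum()
    if total <= 0:
        return np.asarray(v.origin) + (np.asarray(v.shape) - 1) / 2.0 * np.asarray(v.spacing)
    idx = np.array(ndimage.center_of_mass(w))
    return np.asarray(v.origin) + idx * np.asarray(v.spacing)


def rigid_register(moving: Volume, fixed: Volume, max_iter: int = 60) -> RigidTransform:
    """6-dof rigid alignment minimizing mean squared difference.

    Initialized from intensity centroids, then coordinate descent with step
    halving, first on a 2x-subsampled grid and then at full resolution.
    Deterministic.
    """
    center = tuple(_centroid_world(fixed))
    t0 = _centroid_world(moving) - _centroid_world(fixed)
    params = np.array([0.0, 0.0, 0.0, *t0])  # 3 angles (rad), 3 translations (mm)

    def optimize(mov, fix, params, ang_step, tr_step, min_ang, min_tr, sweeps):
        steps = np.array([ang_step] * 3 + [tr_step] * 3)
        minimum = np.array([min_ang] * 3 + [min_tr] * 3)

        def metric(p):
            t = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
            warped = _sample_rigid(mov, fix, t)
            m = float(np.mean((warped - fix.data) ** 2))
            if not np.isfinite(m):
                raise ValidationError("non-finite rigid registration metric")
            return m

        best = metric(params)
        for _ in range(sweeps):
            improved = False
            for i in range(6):
                for sgn in (1.0, -1.0):
                    cand = params.copy()
                    cand[i] += sgn * steps[i]
                    m = metric(cand)
                    if m < best - 1e-15:
                        best, params = m, cand
                        improved = True
                        break
            if not improved:
                steps *= 0.5
                if (steps < minimum).all():
                    break
        return params

    mov2 = resample(moving, 2, "subsample")
    fix2 = resample(fixed, 2, "subsample")
    sp = min(fixed.spacing)
    params = optimize(mov2, fix2, params, 0.08, 2.0 * sp, 0.004, 0.05 * sp, max_iter)
    params = optimize(moving, fixed, params, 0.02, 0.5 * sp, 0.002, 0.02 * sp, max_iter)
    return RigidTransform(tuple(params[:3]), tuple(params[3:]), center)


# ---------------------------------------------------------------------------
# Field composition / inversion


def compose(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Inner-then-outer composition:
    ``disp(x) = disp_outer(x) + disp_inner(x + disp_outer(x))`` (trilinear)."""
    if outer.shape != inner.shape:
        raise ValidationError(f"field shape mismatch: {outer.shape} vs {inner.shape}")
    coords = _identity_coords(outer.shape) + outer.disp
    sampled = np.stack(
        [ndimage.map_coordinates(inner.disp[i], coords, order=1, mode="nearest")
         for i in range(3)]
    )
    return DeformationField(outer.disp + sampled, outer.spacing, outer.origin)


def invert_deformation(d: DeformationField, n_iter: int = 20) -> DeformationField:
    """Approximate inverse by fixed-point iteration: e <- -disp(x + e(x))."""
    inv = np.zeros_like(d.disp)
    idx = _identity_coords(d.shape)
    for _ in range(n_iter):
        coords = idx + inv
        inv = -np.stack(
            [ndimage.map_coordinates(d.disp[i], coords, order=1, mode="nearest")
             for i in range(3)]
        )
    return DeformationField(inv, d.spacing, d.origin)


# ---------------------------------------------------------------------------
# Diffeomorphic (demons-style) registration


def _upsample_field(d: DeformationField, factor_ratio: int, target_shape, spacing, origin):
    """Transfer a displacement field to a finer grid (scale by the factor ratio)."""
    comps = []
    for i in range(3):
        comp = Volume(d.disp[i], (1.0, 1.0, 1.0))
        fine = resample(comp, factor_ratio, "restore", target_shape=target_shape)
        comps.append(fine.data * factor_ratio)
    return DeformationField(np.stack(comps), spacing, origin)


def _msd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def diffeo_register(
    moving: Volume,
    fixed: Volume,
    schedule: Schedule | None = None,
    kappa: float = 1.0,
    fluid_sigma: float = 1.0,
    diffusion_sigma: float = 0.5,
    tol: float = 1e-4,
    step_cap: float = 0.4,
) -> RegResult:
    """Greedy diffeomorphic demons over a coarse-to-fine schedule.

    Per iteration the update is
    ``u = (F - M.phi) * grad(M.phi) / (|grad(M.phi)|^2 + kappa * (F - M.phi)^2)``
    smoothed by ``fluid_sigma`` (voxels), scaled so ``max |u| <= step_cap``,
    composed into the running field, whose displacement is then smoothed by
    ``diffusion_sigma``. A candidate is accepted only if it lowers the MSD and
    keeps the interior Jacobian determinant positive; otherwise the step cap
    is halved and retried. Early stop after 5 iterations with relative
    improvement below ``tol``.
    """
    if moving.shape != fixed.shape:
        raise ValidationError(f"shape mismatch: {moving.shape} vs {fixed.shape}")
    schedule = schedule or Schedule()

    # common intensity scale so kappa is dimensionless
    lo = min(moving.data.min(), fixed.data.min())
    hi = max(moving.data.max(), fixed.data.max())
    scale = (hi - lo) if hi > lo else 1.0
    mov_n = moving.like((moving.data - lo) / scale)
    fix_n = fixed.like((fixed.data - lo) / scale)

    field = None
    prev_factor = None
    trace: list[float] = []
    boundaries: list[int] = []
    converged = False

    for factor, max_iter in schedule.levels:
        fix_l = resample(fix_n, factor, "subsample")
        mov_l = resample(mov_n, factor, "subsample")
        if field is None:
            field = DeformationField.zero(fix_l.shape, fix_l.spacing, fix_l.origin)
        else:
            field = _upsample_field(
                field, prev_factor // factor, fix_l.shape, fix_l.spacing, fix_l.origin
            )
        prev_factor = factor

        idx = _identity_coords(fix_l.shape)

        def warp(f):
            return ndimage.map_coordinates(mov_l.data, idx + f.disp, order=1, mode="nearest")

        warped = warp(field)
        cur = _msd(warped, fix_l.data)
        boundaries.append(len(trace))
        trace.append(cur)
        stall = 0
        cap = step_cap

        for _ in range(max_iter):
            diff = fix_l.data - warped
            grads = np.gradient(warped)
            gsq = grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2
            denom = gsq + kappa * diff**2
            with np.errstate(divide="ignore", invalid="ignore"):
                u = np.stack([np.where(denom > 1e-12, diff * g / denom, 0.0) for g in grads])
            if fluid_sigma > 0:
                u = np.stack([ndimage.gaussian_filter(c, fluid_sigma, mode="nearest") for c in u])
            unorm = np.sqrt((u**2).sum(axis=0)).max()
            if unorm <= 0:
                converged = True
                break

            accepted = False
            local_cap = cap
            for _try in range(4):
                step = u * (min(local_cap / unorm, 1.0) if unorm > local_cap else 1.0)
                upd = DeformationField(step, field.spacing, field.origin)
                cand = compose(upd, field)
                if diffusion_sigma > 0:
                    cand = DeformationField(
                        np.stack([
                            ndimage.gaussian_filter(c, diffusion_sigma, mode="nearest")
                            for c in cand.disp
                        ]),
                        field.spacing,
                        field.origin,
                    )
                cand_warped = warp(cand)
                m = _msd(cand_warped, fix_l.data)
                if m < cur and min_interior_jacobian(cand) > 0:
                    field, warped = cand, cand_warped
                    rel_impr = (cur - m) / max(trace[boundaries[-1]], 1e-30)
                    cur = m
                    trace.append(cur)
                    accepted = True
                    stall = stall + 1 if rel_impr < tol else 0
                    break
                local_cap *= 0.5
            if not accepted or stall >= 5:
                converged = True
                break

    if min_interior_jacobian(field) <= 0:
        raise ValidationError("emitted deformation field has non-positive Jacobian")
    return RegResult(field=field, metric_trace=trace, level_boundaries=boundaries,
                     converged=converged)
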