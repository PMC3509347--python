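"""Iterative population template, probabilistic label maps, ROI search boxes."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import SubjectCase
from .register import RegResult, Schedule, apply_rigid, diffeo_register, rigid_register
from .volumes import (
    DeformationField,
    LabelMap,
    ValidationError,
    Volume,
    apply_deformation,
    gaussian_smooth,
    read_volume,
    write_volume,
)

__all__ = [
    "Template",
    "build_template",
    "probabilistic_label_map",
    "amygdala_roi",
    "save_template",
    "load_template",
]

log = logging.getLogger(__name__)

STRUCTURE_LABELS = (1, 2)  # left, right


@dataclass
class Template:
    image: Volume
    prob_labels: dict  # structure label -> probability Volume in [0, 1]
    roi_boxes: dict  # structure label -> ((lo0,lo1,lo2), (hi0,hi1,hi2)), half-open
    # per-training-subject data in template space, reused by the pipeline:
    atlas_images: dict = field(default_factory=dict)  # id -> Volume
    atlas_labels: dict = field(default_factory=dict)  # id -> LabelMap
    msd_trace: list = field(default_factory=list)  # mean final MSD per outer iteration


def probabilistic_label_map(warped_labels: list, sigma_mm: float = 1.0) -> dict:
    """Per structure: mean of binary masks across subjects, smoothed by a
    Gaussian of ``sigma_mm``, clipped to [0, 1]."""
    if not warped_labels:
        raise ValidationError("no label maps given")
    ref = warped_labels[0]
    for lm in warped_labels:
        if lm.shape != ref.shape:
            raise ValidationError("label maps are not on a common grid")
    out = {}
    for s in STRUCTURE_LABELS:
        mean = np.mean([lm.binary(s).astype(float) for lm in warped_labels], axis=0)
        vol = Volume(mean, ref.spacing, ref.origin)
        if sigma_mm > 0:
            vol = gaussian_smooth(vol, sigma_mm)
        out[s] = vol.like(np.clip(vol.data, 0.0, 1.0))
    return out


def amygdala_roi(prob: Volume, threshold: float = 0.01, margin_mm: float = 4.0):
    """Half-open bounding box of ``{prob > threshold}`` dilated by
    ``margin_mm`` (rounded up to voxels per axis), clipped to the grid."""
    sup = prob.data > threshold
    if not sup.any():
        raise ValidationError(f"probability map has no support above {threshold}")
    idx = np.nonzero(sup)
    lo = np.array([a.min() for a in idx])
    hi = np.array([a.max() for a in idx]) + 1
    margin = np.array([int(np.ceil(margin_mm / s)) for s in prob.spacing])
    lo = np.maximum(lo - margin, 0)
    hi = np.minimum(hi + margin, prob.shape)
    return (tuple(int(x) for x in lo), tuple(int(x) for x in hi))


def build_template(
    train: list[SubjectCase],
    n_outer: int = 3,
    schedule: Schedule | None = None,
    reg_params: dict | None = None,
    label_sigma_mm: float = 1.0,
    roi_threshold: float = 0.01,
    roi_margin_mm: float = 4.0,
) -> Template:
    """Iterative unbiased template from >= 2 (intensity-normalized) subjects.

    Initialization: voxelwise mean after rigid alignment of every subject to
    subject 1. Each outer iteration diffeomorphically registers every subject
    to the current template, averages the warped images, and removes the mean
    displacement (demeaning) to keep the template unbiased. Final fields
    transport each subject's labels; the averaged masks are smoothed into
    probability maps from which per-structure ROI boxes are derived.
    """
    if len(train) < 2:
        raise ValidationError("template construction needs >= 2 training subjects")
    schedule = schedule or Schedule()
    reg_params = reg_params or {}

    ref = train[0].image
    rigids = {}
    aligned_imgs, aligned_lbls = {}, {}
    for case in train:
        t = rigid_register(case.image, ref)
        rigids[case.id] = t
        aligned_imgs[case.id] = apply_rigid(case.image, t, ref)
        aligned_lbls[case.id] = apply_rigid(case.truth, t, ref, interp="nearest")

    template_img = ref.like(np.mean([aligned_imgs[c.id].data for c in train], axis=0))

    fields: dict[str, DeformationField] = {}
    msd_trace = []
    for it in range(n_outer):
        warped = []
        finals = []
        for case in train:
            res: RegResult = diffeo_register(
                aligned_imgs[case.id], template_img, schedule, **reg_params
            )
            fields[case.id] = res.field
            warped.append(apply_deformation(aligned_imgs[case.id], res.field))
            finals.append(res.metric_trace[-1])
        msd_trace.append(float(np.mean(finals)))
        avg = ref.like(np.mean([w.data for w in warped], axis=0))
        mean_disp = np.mean([fields[c.id].disp for c in train], axis=0)
        # unbias: pull the average back along the (negated) mean displacement
        demean = DeformationField(-mean_disp, ref.spacing, ref.origin)
        template_img = apply_deformation(avg, demean)
        log.info("template outer iteration %d: mean final MSD %.6g", it + 1, msd_trace[-1])

    warped_labels = [
        apply_deformation(aligned_lbls[c.id], fields[c.id], "nearest") for c in train
    ]
    prob = probabilistic_label_map(warped_labels, sigma_mm=label_sigma_mm)
    rois = {
        s: amygdala_roi(prob[s], threshold=roi_threshold, margin_mm=roi_margin_mm)
        for s in STRUCTURE_LABELS
    }
    atlas_images = {
        c.id: apply_deformation(aligned_imgs[c.id], fields[c.id]) for c in train
    }
    atlas_labels = {c.id: wl for c, wl in zip(train, warped_labels)}
    return Template(
        image=template_img,
        prob_labels=prob,
        roi_boxes=rois,
        atlas_images=atlas_images,
        atlas_labels=atlas_labels,
        msd_trace=msd_trace,
    )


def save_template(t: Template, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(t.image, out / "image.nii.gz")
    names = {1: "prob_L.nii.gz", 2: "prob_R.nii.gz"}
    for s, vol in t.prob_labels.items():
        write_volume(vol, out / names[s])
    (out / "rois.json").write_text(
        json.dumps({str(s): [list(lo), list(hi)] for s, (lo, hi) in t.roi_boxes.items()},
                   indent=2)
    )
    for sid in t.atlas_images:
        write_volume(t.atlas_images[sid], out / f"atlas_{sid}_image.nii.gz")
        write_volume(t.atlas_labels[sid], out / f"atlas_{sid}_labels.nii.gz")


def load_template(tmpl_dir) -> Template:
    from .volumes import read_labels

    d = Path(tmpl_dir)
    image = read_volume(d / "image.nii.gz")
    prob = {1: read_volume(d / "prob_L.nii.gz"), 2: read_volume(d / "prob_R.nii.gz")}
    rois = {
        int(s): (tuple(lo), tuple(hi))
        for s, (lo, hi) in json.loads((d / "rois.json").read_text()).items()
    }
    atlas_images, atlas_labels = {}, {}
    for p in sorted(d.glob("atlas_*_image.nii.gz")):
        sid = p.name[len("atlas_"):-len("_image.nii.gz")]
        atlas_images[sid] = read_volume(p)
        atlas_labels[sid] = read_labels(d / f"atlas_{sid}_labels.nii.gz")
    return Template(image=image, prob_labels=prob, roi_boxes=rois,
                    atlas_images=atlas_images, atlas_labels=atlas_labels)
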