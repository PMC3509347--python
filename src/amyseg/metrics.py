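"""Segmentation agreement battery: Dice/Jaccard overlap, volume correlation
and two-way single-measures intraclass correlations, with cohort reporting."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import LabelMap, ValidationError

__all__ = ["dice", "jaccard", "pearson", "icc", "MetricsReport", "evaluate_cohort"]

STRUCTURE_LABELS = (1, 2)
STRUCTURE_NAMES = {1: "left", 2: "right"}


def _check_grids(a: LabelMap, b: LabelMap):
    if a.shape != b.shape:
        raise ValidationError(f"grid mismatch: {a.shape} vs {b.shape}")


def dice(a: LabelMap, b: LabelMap, label: int) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    _check_grids(a, b)
    am = a.labels == label
    bm = b.labels == label
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


def jaccard(a: LabelMap, b: LabelMap, label: int) -> float:
    """Jaccard overlap |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    _check_grids(a, b)
    am = a.labels == label
    bm = b.labels == label
    union = int((am | bm).sum())
    if union == 0:
        return 1.0
    return int((am & bm).sum()) / union


def pearson(x, y) -> float:
    """Sample Pearson correlation; requires n >= 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson needs two equal-length 1-D lists, n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = (xc**2).sum()
    vy = (yc**2).sum()
    if vx == 0 or vy == 0:
        raise ValidationError("zero variance input to pearson")
    return float((xc * yc).sum() / np.sqrt(vx * vy))


def icc(ratings: np.ndarray, kind: str = "consistency") -> float:
    """Two-way single-measures intraclass correlation for an n x 2 table.

    consistency: (MSR - MSE) / (MSR + (k-1) MSE)
    absolute:    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    with mean squares from the two-way ANOVA decomposition.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2 or r.shape[0] < 3:
        raise ValidationError("icc needs an (n >= 3) x 2 ratings table")
    if kind not in ("consistency", "absolute"):
        raise ValidationError(f"unknown ICC kind {kind!r}")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((r - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if kind == "absolute":
        denom = denom + (k / n) * (msc - mse)
    if abs(denom) < 1e-300:
        raise ValidationError("degenerate ratings table (zero ICC denominator)")
    return float((msr - mse) / denom)


@dataclass
class MetricsReport:
    per_subject: pd.DataFrame  # subject, structure, dice, jaccard, auto/reference volumes
    cohort: dict  # per structure: pearson_r, icc_consistency, icc_absolute, means/sds

    def to_csv(self, path) -> None:
        self.per_subject.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "per_subject": self.per_subject.to_dict(orient="records"),
            "cohort": self.cohort,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate_cohort(auto: dict, reference: dict,
                    labels=STRUCTURE_LABELS) -> MetricsReport:
    """Full agreement report for matched cohorts.

    ``auto`` and ``reference`` map subject id -> LabelMap. Row metrics are
    Dice, Jaccard (with the identity J = D/(2-D)) and volumes in mm^3;
    cohort summaries add Pearson r and both ICCs over volumes per structure.
    """
    unmatched = set(auto) ^ set(reference)
    if unmatched:
        raise ValidationError(f"unmatched subject ids: {sorted(unmatched)}")
    rows = []
    for sid in sorted(auto):
        a, r = auto[sid], reference[sid]
        for s in labels:
            rows.append({
                "subject": sid,
                "structure": STRUCTURE_NAMES.get(s, str(s)),
                "label": s,
                "dice": dice(a, r, s),
                "jaccard": jaccard(a, r, s),
                "auto_volume_mm3": a.volume_mm3(s),
                "reference_volume_mm3": r.volume_mm3(s),
            })
    df = pd.DataFrame(rows)
    cohort = {}
    for s in labels:
        sub = df[df["label"] == s]
        entry = {
            "dice_mean": float(sub["dice"].mean()),
            "dice_sd": float(sub["dice"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "jaccard_mean": float(sub["jaccard"].mean()),
            "jaccard_sd": float(sub["jaccard"].std(ddof=1)) if len(sub) > 1 else 0.0,
        }
        av = sub["auto_volume_mm3"].to_numpy()
        rv = sub["reference_volume_mm3"].to_numpy()
        if len(sub) >= 3:
            table = np.column_stack([rv, av])
            try:
                entry["pearson_r"] = pearson(rv, av)
            except ValidationError:
                entry["pearson_r"] = float("nan")
            try:
                entry["icc_consistency"] = icc(table, "consistency")
                entry["icc_absolute"] = icc(table, "absolute")
            except ValidationError:
                entry["icc_consistency"] = float("nan")
                entry["icc_absolute"] = float("nan")
        cohort[STRUCTURE_NAMES.get(s, str(s))] = entry
    return MetricsReport(per_subject=df, cohort=cohort)
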