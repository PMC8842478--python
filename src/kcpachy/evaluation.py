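"""Segmentation-quality metrics against reference masks and profiles.

Overlap metrics (Dice, IoU, sensitivity, specificity) compare candidate and
reference label masks per pixel for a target class — the epithelium alone or
the whole cornea (epithelium plus stroma).  The indirect metric is the
thickness error: the mean absolute difference between candidate and reference
40-point thickness profiles, in um.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .boundaries import mask_from_boundaries, trace_from_image, trace_from_mask
from .errors import KcpachyError
from .geometry import StageLabel
from .pachymetry import ThicknessProfile, measure_profile
from .phantom import EPITHELIUM, STROMA, EyeRecord, LabelMask, render_bscan

TargetClass = Literal["epithelium", "cornea"]


@dataclass(frozen=True)
class SegMetrics:
    """Overlap and thickness-error metrics for one tissue class."""

    dice: float
    iou: float
    sensitivity: float
    specificity: float
    t_error: float = float("nan")  # um


def _class_mask(labels: np.ndarray, target: TargetClass) -> np.ndarray:
    if target == "epithelium":
        return labels == EPITHELIUM
    if target == "cornea":
        return (labels == EPITHELIUM) | (labels == STROMA)
    raise ValueError(f"target must be 'epithelium' or 'cornea', got {target!r}")


def overlap_metrics(
    candidate: LabelMask, reference: LabelMask, target: TargetClass
) -> tuple[float, float, float, float]:
    """(dice, iou, sensitivity, specificity) of one class over pixels.

    Specificity counts background pixels of the full grid as negatives.
    Raises on grid mismatch or an empty reference class.
    """
    if candidate.labels.shape != reference.labels.shape:
        raise ValueError("candidate and reference grids differ in shape")
    a = _class_mask(candidate.labels, target)
    b = _class_mask(reference.labels, target)
    if not b.any():
        raise KcpachyError(f"reference contains no {target} pixels; metrics undefined")
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    tn = int((~a & ~b).sum())
    dice = 2 * tp / (2 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return dice, iou, sens, spec


def thickness_error(
    candidate: Iterable[ThicknessProfile],
    reference: Iterable[ThicknessProfile],
) -> float:
    """Mean absolute thickness difference (um) over matched profile samples."""
    cand = list(candidate)
    ref = list(reference)
    if len(cand) != len(ref):
        raise ValueError("candidate and reference profile counts differ")
    diffs = []
    for c, r in zip(cand, ref):
        if not np.allclose(c.positions, r.positions):
            raise ValueError("profile position grids differ")
        diffs.append(np.abs(c.values - r.values))
    return float(np.concatenate(diffs).mean())


def evaluate_extractor(
    cohort: Sequence[EyeRecord],
    mode: Literal["mask", "image"] = "mask",
    seed: int = 0,
) -> pd.DataFrame:
    """Score a boundary-extraction path against the generating masks.

    For every scan the candidate boundaries come from the chosen path (mask
    tracing, or gradient extraction on a rendered B-scan); overlap metrics
    compare the re-rasterized candidate against the generating mask, and the
    thickness error compares measured profiles.  Metrics are averaged per
    image first, then per (stage group, tissue) cell.
    """
    if not cohort:
        raise KcpachyError("cohort is empty")
    rows = []
    for eye in cohort:
        for meridian in ("H", "V"):
            ref_mask = eye.mask(meridian)
            if mode == "mask":
                bset = trace_from_mask(ref_mask)
            elif mode == "image":
                img = render_bscan(eye.truth(meridian), eye.geometry, seed=seed)
                bset = trace_from_image(img, eye.geometry)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            bset.laterality, bset.meridian = eye.laterality, meridian
            cand_mask = mask_from_boundaries(bset)
            cand_epi, cand_cor = measure_profile(bset, eye.eye_id, eye.stage)
            ref_bset = trace_from_mask(ref_mask)
            ref_bset.laterality, ref_bset.meridian = eye.laterality, meridian
            ref_epi, ref_cor = measure_profile(ref_bset, eye.eye_id, eye.stage)
            for target, cand_p, ref_p in (
                ("epithelium", cand_epi, ref_epi),
                ("cornea", cand_cor, ref_cor),
            ):
                d, i, sn, sp = overlap_metrics(cand_mask, ref_mask, target)
                rows.append(
                    dict(
                        eye_id=eye.eye_id,
                        stage=eye.stage.name,
                        group="Normal" if eye.stage == StageLabel.normal else "KC",
                        meridian=meridian,
                        tissue=target,
                        dice=d,
                        iou=i,
                        sensitivity=sn,
                        specificity=sp,
                        t_error=thickness_error([cand_p], [ref_p]),
                    )
                )
    per_image = pd.DataFrame(rows)
    metrics = ["dice", "iou", "sensitivity", "specificity", "t_error"]
    return (
        per_image.groupby(["tissue", "group"], sort=False)[metrics]
        .mean()
        .reset_index()
    )
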