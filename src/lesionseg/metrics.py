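"""Lesion-level detection and voxel-level segmentation scoring.

Detection works on lesion objects (connected components), segmentation on
voxels. With lesion counts TP_l, FP_l, FN_l and voxel counts TP_v, FP_v,
FN_v:

    F1        = 2 TP_l / (FP_l + 2 TP_l + FN_l)
    recall    = TP_l / (TP_l + FN_l)
    precision = TP_l / (TP_l + FP_l)
    Dice      = 2 TP_v / (FP_v + 2 TP_v + FN_v)

A ground-truth lesion counts as detected (TP) when the predicted
foreground covers at least ``min_overlap_fraction`` of its voxels; a
predicted lesion counts as a false positive when it overlaps no
ground-truth lesion in a single voxel. This matching dialect follows the
detection-criteria lineage of the challenge-style segmentation performance
analyzers ("Anima-like") but is configurable and not claimed byte-exact.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .triplanar import LesionSet, label_lesions
from .volume_io import BinaryMask3D, GeometryError

__all__ = ["MatchConfig", "DetectionReport", "match_lesions",
           "detection_scores", "evaluate_masks", "evaluate_cohort"]


@dataclasses.dataclass(frozen=True)
class MatchConfig:
    min_overlap_fraction: float = 0.10
    min_lesion_volume_mm3: float = 0.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")


@dataclasses.dataclass
class DetectionReport:
    TP_l: int
    FP_l: int
    FN_l: int
    TP_v: int
    FP_v: int
    FN_v: int
    f1: float
    recall: float
    precision: float
    dice: float
    empty_vs_empty: bool = False
    subject: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def match_lesions(pred: LesionSet, gt: LesionSet,
                  config: MatchConfig = MatchConfig()) -> list[dict]:
    """Per-lesion match table for one prediction/ground-truth pair.

    Rows carry ``side`` ("gt" or "pred"), lesion id, overlap fraction
    (for GT lesions: fraction covered by the predicted foreground), and
    status ("TP", "FN", or "FP").
    """
    if pred.labels.shape != gt.labels.shape:
        raise GeometryError("prediction and ground truth are on different grids")
    pred_fg = pred.labels > 0
    gt_fg = gt.labels > 0
    table = []
    for les in gt.lesions:
        if les["volume_mm3"] < config.min_lesion_volume_mm3:
            continue
        sel = gt.labels == les["id"]
        frac = float((sel & pred_fg).sum()) / float(sel.sum())
        status = "TP" if frac >= config.min_overlap_fraction else "FN"
        table.append({"side": "gt", "id": les["id"], "overlap": frac,
                      "status": status})
    for les in pred.lesions:
        if les["volume_mm3"] < config.min_lesion_volume_mm3:
            continue
        sel = pred.labels == les["id"]
        touches = bool((sel & gt_fg).any())
        if not touches:
            table.append({"side": "pred", "id": les["id"], "overlap": 0.0,
                          "status": "FP"})
    return table


def detection_scores(table: list[dict], pred_mask: np.ndarray | None = None,
                     gt_mask: np.ndarray | None = None,
                     subject: str = "") -> DetectionReport:
    """Scores from a match table plus (optional) voxel confusion counts.

    The empty-vs-empty case (no lesions on either side) reports every
    score as 1 and sets a flag; empty prediction against nonempty ground
    truth gives recall 0.
    """
    tp_l = sum(1 for r in table if r["status"] == "TP")
    fn_l = sum(1 for r in table if r["status"] == "FN")
    fp_l = sum(1 for r in table if r["status"] == "FP")
    if pred_mask is not None and gt_mask is not None:
        p = pred_mask > 0
        g = gt_mask > 0
        tp_v = int((p & g).sum())
        fp_v = int((p & ~g).sum())
        fn_v = int((~p & g).sum())
    else:
        tp_v = fp_v = fn_v = 0

    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else 1.0

    empty = (tp_l + fn_l + fp_l == 0) and (tp_v + fn_v + fp_v == 0)
    return DetectionReport(
        TP_l=tp_l, FP_l=fp_l, FN_l=fn_l, TP_v=tp_v, FP_v=fp_v, FN_v=fn_v,
        f1=safe(2 * tp_l, fp_l + 2 * tp_l + fn_l),
        recall=safe(tp_l, tp_l + fn_l),
        precision=safe(tp_l, tp_l + fp_l),
        dice=safe(2 * tp_v, fp_v + 2 * tp_v + fn_v),
        empty_vs_empty=empty, subject=subject)


def evaluate_masks(pred: BinaryMask3D, gt: BinaryMask3D,
                   config: MatchConfig = MatchConfig(),
                   subject: str = "") -> DetectionReport:
    """Convenience: label both masks, match, and score in one call."""
    if pred.shape != gt.shape:
        raise GeometryError("prediction and ground truth are on different grids")
    table = match_lesions(label_lesions(pred, config.connectivity),
                          label_lesions(gt, config.connectivity), config)
    return detection_scores(table, pred.data, gt.data, subject=subject)


def evaluate_cohort(pairs: list[tuple[BinaryMask3D, BinaryMask3D]],
                    config: MatchConfig = MatchConfig(),
                    exclude_empty_gt: bool = True
                    ) -> tuple[list[DetectionReport], dict]:
    """Per-subject reports and the unweighted mean across subjects.

    With ``exclude_empty_gt`` (the challenge-style scoring), subjects whose
    ground truth has no lesion are listed but omitted from the means.
    """
    if not pairs:
        raise ValueError("need at least one subject")
    reports = []
    for i, (pred, gt) in enumerate(pairs):
        reports.append(evaluate_masks(pred, gt, config,
                                      subject=gt.id or f"subject{i}"))
    included = [r for r in reports
                if not (exclude_empty_gt and r.TP_l + r.FN_l == 0)]
    pool = included or reports
    mean = {m: float(np.mean([getattr(r, m) for r in pool]))
            for m in ("f1", "recall", "precision", "dice")}
    mean["n_subjects"] = len(pool)
    mean["n_excluded"] = len(reports) - len(included)
    return reports, mean
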