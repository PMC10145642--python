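"""Segmentation and detection evaluation.

Pixelwise segmentation metrics (precision, recall, F-measure, Dice,
Jaccard) and point-based detection metrics (match predicted component
centroids to ground-truth centres within a radius).  For binary pixel
masks the F-measure and the Dice coefficient are the same quantity,
``2TP / (2TP + FP + FN)``, and Jaccard relates to Dice as
``J = D / (2 - D)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skimage import measure

from .exceptions import ConfigError, InvalidInputError

__all__ = ["EvalReport", "segmentation_metrics", "detection_metrics"]


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    dice: float
    jaccard: float


def _report(tp: int, fp: int, fn: int) -> EvalReport:
    if tp == 0 and fp == 0 and fn == 0:
        # empty prediction vs empty truth: perfect by convention
        return EvalReport(0, 0, 0, 1.0, 1.0, 1.0, 1.0, 1.0)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    dice = 2 * tp / (2 * tp + fp + fn)
    jaccard = tp / (tp + fp + fn) if tp + fp + fn > 0 else 0.0
    return EvalReport(int(tp), int(fp), int(fn), precision, recall, f, dice, jaccard)


def segmentation_metrics(pred: np.ndarray, gt: np.ndarray) -> EvalReport:
    """Pixelwise overlap metrics between a predicted and a truth mask."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise InvalidInputError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return _report(tp, fp, fn)


def detection_metrics(pred: np.ndarray, gt_centres, match_radius: float = 8.0) -> EvalReport:
    """Centre-detection metrics.

    Predicted centres are the centroids of the 8-connected components of
    ``pred``.  Each ground-truth centre (x, y) is greedily matched, in
    order, to the nearest still-unmatched predicted centre within
    ``match_radius`` pixels.  TP = matches, FP = unmatched predictions,
    FN = unmatched ground-truth centres.
    """
    if match_radius <= 0:
        raise ConfigError(f"match_radius must be > 0, got {match_radius}")
    pred = np.asarray(pred, dtype=bool)
    labels = measure.label(pred, connectivity=2)
    # regionprops centroids are (row, col); convert to (x, y)
    pred_centres = np.array(
        [(c[1], c[0]) for c in (r.centroid for r in measure.regionprops(labels))]
    ).reshape(-1, 2)
    gt_centres = np.asarray(gt_centres, dtype=np.float64).reshape(-1, 2)
    if len(gt_centres) == 0:
        return _report(0, len(pred_centres), 0)
    if len(pred_centres) == 0:
        return _report(0, 0, len(gt_centres))
    d = cdist(gt_centres, pred_centres)
    matched_pred: set[int] = set()
    tp = 0
    for gi in range(len(gt_centres)):
        order = np.argsort(d[gi])
        for pj in order:
            if d[gi, pj] > match_radius:
                break
            if pj not in matched_pred:
                matched_pred.add(int(pj))
                tp += 1
                break
    fp = len(pred_centres) - tp
    fn = len(gt_centres) - tp
    return _report(tp, fp, fn)
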