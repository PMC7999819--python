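"""Pixel-wise binary cross-entropy loss and the six segmentation metrics.

The loss is the mean per-pixel binary cross-entropy between a {0,1} ground
truth mask ``x`` and a predicted probability map ``x_hat``:

    H = (1/|Omega|) * sum_j -[(1 - x_j) log(1 - x_hat_j) + x_j log(x_hat_j)]

with predictions clipped to [eps, 1 - eps] (eps = 1e-7) before the logs.

The metrics derive from the pixel confusion counts TP/TN/FP/FN:

    AC = (TP+TN)/(TP+TN+FP+FN)    SE = TP/(TP+FN)    SP = TN/(TN+FP)
    PC = TP/(TP+FP)    F1 = 2*PC*SE/(PC+SE)    JS = TP/(TP+FP+FN)

F1 is the Dice coefficient and JS the Jaccard index (intersection over
union); the two are linked by F1 = 2*JS/(1+JS).  Zero denominators follow
the standard challenge convention: an empty ground truth with an empty
prediction scores 1.0 on SE/PC/F1/JS, while predicted positives against an
empty ground truth score 0.0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EPS = 1e-7
METRIC_NAMES = ("AC", "SE", "SP", "PC", "F1", "JS")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def cross_entropy_loss(pred_prob: np.ndarray, gt: np.ndarray, eps: float = EPS) -> float:
    """Mean per-pixel binary cross-entropy; always finite and non-negative."""
    pred_prob = np.asarray(pred_prob, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    _check_same_shape(pred_prob, gt)
    p = np.clip(pred_prob, eps, 1.0 - eps)
    per_pixel = -((1.0 - gt) * np.log1p(-p) + gt * np.log(p))
    return float(per_pixel.mean())


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion tallies; the four counts partition the image domain."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(gt: np.ndarray, pred_bin: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN pixels between two binary masks."""
    gt = _check_binary(gt, "gt")
    pred = _check_binary(pred_bin, "pred_bin")
    _check_same_shape(gt, pred)
    tp = int(np.count_nonzero(gt & pred))
    tn = int(np.count_nonzero(~gt & ~pred))
    fp = int(np.count_nonzero(~gt & pred))
    fn = int(np.count_nonzero(gt & ~pred))
    return ConfusionCounts(tp, tn, fp, fn)


def _safe_div(num: float, den: float, empty_value: float) -> float:
    return num / den if den > 0 else empty_value


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """The six metrics from confusion counts, with degenerate-case conventions.

    If there are neither true positives nor any claimed/missed positives
    (empty ground truth, empty prediction), the overlap metrics SE/PC/F1/JS
    are 1.0; positives claimed where none exist (or all missed) give 0.0.
    """
    ac = _safe_div(c.tp + c.tn, c.total, 1.0)
    se = _safe_div(c.tp, c.tp + c.fn, 1.0 if c.fp == 0 else 0.0)
    sp = _safe_div(c.tn, c.tn + c.fp, 1.0 if c.fn == 0 else 0.0)
    pc = _safe_div(c.tp, c.tp + c.fp, 1.0 if c.fn == 0 else 0.0)
    if c.tp + c.fp + c.fn == 0:
        f1 = js = 1.0
    else:
        js = c.tp / (c.tp + c.fp + c.fn)
        f1 = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
    return {"AC": ac, "SE": se, "SP": sp, "PC": pc, "F1": f1, "JS": js}


def metrics(gt: np.ndarray, pred_bin: np.ndarray) -> dict[str, float]:
    """AC, SE, SP, PC, F1 (Dice) and JS (Jaccard) for one mask pair."""
    return metrics_from_counts(confusion(gt, pred_bin))


def dice(gt: np.ndarray, pred_bin: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) (equals the F1 metric)."""
    return metrics(gt, pred_bin)["F1"]


def jaccard(gt: np.ndarray, pred_bin: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|."""
    return metrics(gt, pred_bin)["JS"]


def batch_dice(gt: np.ndarray, pred_bin: np.ndarray) -> float:
    """Mean per-image Dice over a batch of masks (B, H, W)."""
    return float(np.mean([dice(g, p) for g, p in zip(gt, pred_bin)]))


def aggregate_metrics(per_image: list[dict[str, float]],
                      counts: list[ConfusionCounts] | None = None,
                      pooled: bool = False) -> dict[str, float]:
    """Aggregate per-image metric dicts.

    ``pooled=False`` (default, the challenge convention) averages each metric
    over images; ``pooled=True`` recomputes the metrics from the summed pixel
    confusion counts and requires ``counts``.
    """
    if pooled:
        if counts is None:
            raise ValueError("pooled aggregation requires the per-image confusion counts")
        total = ConfusionCounts(sum(c.tp for c in counts), sum(c.tn for c in counts),
                                sum(c.fp for c in counts), sum(c.fn for c in counts))
        return metrics_from_counts(total)
    return {k: float(np.mean([m[k] for m in per_image])) for k in METRIC_NAMES}


def write_report(rows: list[dict], csv_path: str | Path, json_path: str | Path,
                 summary: dict[str, float]) -> None:
    """Write the per-image CSV (filename + six metrics) and the JSON summary."""
    csv_path, json_path = Path(csv_path), Path(json_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["filename", *METRIC_NAMES])
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in ("filename", *METRIC_NAMES)})
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
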