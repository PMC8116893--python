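"""Overlap and lesion-wise detection metrics.

DSC is the voxel-overlap Dice coefficient.  Lesion detection works on
26-connected components: a true lesion counts as detected when at least one
voxel overlaps a predicted component; the lesion-wise FPR is the fraction of
predicted components with no truth overlap (documented explicitly because
challenge conventions differ); F combines precision ``P = 1 - FPR`` and
recall ``R = TPR``.

Empty-set conventions (logged in every report): both masks empty -> DSC 1,
TPR 1, FPR 0; prediction empty with non-empty truth -> TPR 0, FPR 0, F 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .inference import SegmentationResult
from .volumes import LabelMap

__all__ = ["MetricReport", "dice", "lesion_detection_metrics", "evaluate_case"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MetricReport:
    mode: str
    dsc_per_class: dict[int, float] = field(default_factory=dict)
    dsc_mean: float = float("nan")
    tpr: float = float("nan")
    fpr: float = float("nan")
    f_score: float = float("nan")
    counts: dict[str, int] = field(default_factory=dict)

    def rows(self) -> list[dict]:
        """Per-metric rows suitable for CSV export."""
        out = [{"metric": f"dsc_class_{c}", "value": v} for c, v in self.dsc_per_class.items()]
        out.append({"metric": "dsc_mean", "value": self.dsc_mean})
        if self.mode == "lesions":
            out += [{"metric": "tpr", "value": self.tpr},
                    {"metric": "fpr", "value": self.fpr},
                    {"metric": "f_score", "value": self.f_score}]
        return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|a∩b| / (|a|+|b|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def lesion_detection_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float, dict]:
    """Component-wise TPR, FPR and F-score (see module docstring)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    t_comp, nt = ndimage.label(truth, structure=_CONN26)
    p_comp, npred = ndimage.label(pred, structure=_CONN26)
    detected = 0
    for c in range(1, nt + 1):
        if pred[t_comp == c].any():
            detected += 1
    false_pos = 0
    for c in range(1, npred + 1):
        if not truth[p_comp == c].any():
            false_pos += 1
    counts = {"truth_lesions": nt, "pred_components": npred,
              "detected": detected, "false_positive_components": false_pos}
    if nt == 0 and npred == 0:
        return 1.0, 0.0, 1.0, counts
    tpr = detected / nt if nt else 1.0
    fpr = false_pos / npred if npred else 0.0
    precision = 1.0 - fpr
    f = 0.0 if (precision + tpr) == 0 else 2 * precision * tpr / (precision + tpr)
    return tpr, fpr, f, counts


def evaluate_case(result: SegmentationResult, truth: LabelMap,
                  mode: str = "structures") -> MetricReport:
    """Per-class DSC (structures) or DSC + detection metrics (lesions)."""
    pred = result.labels
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth geometries differ")
    if mode == "structures":
        if pred.class_count != truth.class_count:
            raise ValueError(
                f"class count mismatch: {pred.class_count} vs {truth.class_count}")
        per_class = {
            c: dice(pred.data == c, truth.data == c)
            for c in range(1, truth.class_count)
        }
        mean = float(np.mean(list(per_class.values()))) if per_class else float("nan")
        return MetricReport(mode=mode, dsc_per_class=per_class, dsc_mean=mean)
    if mode == "lesions":
        pm = pred.data == 1
        tm = truth.data == 1
        d = dice(pm, tm)
        tpr, fpr, f, counts = lesion_detection_metrics(pm, tm)
        return MetricReport(mode=mode, dsc_per_class={1: d}, dsc_mean=d,
                            tpr=tpr, fpr=fpr, f_score=f, counts=counts)
    raise ValueError(f"unknown mode {mode!r}")
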