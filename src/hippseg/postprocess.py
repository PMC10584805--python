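"""Voxel decisions, connected-component filtering, and evaluation metrics.

Decision rule per voxel: if the summed foreground probability
``P_ant + P_pos`` exceeds 0.5 the voxel takes the foreground class with the
larger probability (ties to anterior); otherwise it is background.

Connected-component filtering pools classes 1 and 2 into a single
foreground, labels components under 26-connectivity, and removes every
component smaller than 27 voxels (a 3x3x3 cube is the smallest acceptable
component); surviving voxels keep their class.

Metrics: per-class and averaged Dice similarity coefficient (DSC), positive
predictive value (PPV) and sensitivity (SEN) from binary confusion counts,
with a smoothing constant 1e-5 keeping all ratios defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_volumes import LabelVolume

__all__ = [
    "ProbabilityVolume", "MetricsResult", "voxel_decision", "cca_filter",
    "postprocess_volume", "confusion_counts", "segmentation_metrics",
    "evaluate_pair",
]

CCA_THRESHOLD = 27
SMOOTH = 1e-5
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities (background, anterior, posterior).

    ``probs`` has shape (3, W, H, D) and sums to 1 per voxel.
    """

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4 or self.probs.shape[0] != 3:
            raise ValueError(
                f"expected (3, W, H, D) probabilities, got {self.probs.shape}")
        if self.probs.min() < -1e-6 or self.probs.max() > 1 + 1e-6:
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-5:
            raise ValueError("per-voxel probabilities do not sum to 1")

    @property
    def p_bac(self):
        return self.probs[0]

    @property
    def p_ant(self):
        return self.probs[1]

    @property
    def p_pos(self):
        return self.probs[2]


@dataclass
class MetricsResult:
    """DSC/PPV/SEN per class and averaged, plus the underlying counts."""

    per_class: dict = field(default_factory=dict)  # cls -> {dsc,ppv,sen}
    counts: dict = field(default_factory=dict)     # cls -> (TP,FP,FN,TN)
    smooth: float = SMOOTH

    @property
    def average(self) -> dict:
        keys = ("dsc", "ppv", "sen")
        return {k: float(np.mean([self.per_class[c][k]
                                  for c in self.per_class])) for k in keys}


def voxel_decision(p_ant, p_pos, p_bac):
    """Classify voxels from probability triples (vectorized).

    Returns 1 (anterior) or 2 (posterior) where ``p_ant + p_pos > 0.5``
    (the foreground class with the larger probability; exact ties go to
    anterior), else 0 (background).
    """
    p_ant = np.asarray(p_ant, dtype=np.float64)
    p_pos = np.asarray(p_pos, dtype=np.float64)
    fg = (p_ant + p_pos) > 0.5
    cls = np.where(p_ant >= p_pos, 1, 2).astype(np.int16)
    out = np.where(fg, cls, 0).astype(np.int16)
    return out if out.ndim else int(out)


def cca_filter(l: LabelVolume, threshold: int = CCA_THRESHOLD,
               connectivity: int = 26) -> LabelVolume:
    """Remove small foreground islands.

    Classes 1 and 2 are pooled as foreground before component labeling so
    the two adjacent lobes count as one structure; components with fewer
    than ``threshold`` voxels are set to background.  Never adds foreground;
    idempotent.
    """
    if connectivity == 26:
        structure = _STRUCT26
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    values = l.values.copy()
    fg = values > 0
    comp, n = ndimage.label(fg, structure=structure)
    if n:
        sizes = np.bincount(comp.ravel())
        kill = np.isin(comp, np.nonzero(sizes < threshold)[0]) & fg
        values[kill] = 0
    return LabelVolume(values=values, spacing=l.spacing, affine=l.affine)


def postprocess_volume(p: ProbabilityVolume,
                       threshold: int = CCA_THRESHOLD) -> LabelVolume:
    """Voxel decision followed by connected-component filtering."""
    decided = voxel_decision(p.p_ant, p.p_pos, p.p_bac)
    return cca_filter(LabelVolume(values=decided), threshold=threshold)


def confusion_counts(pred: LabelVolume | np.ndarray,
                     gt: LabelVolume | np.ndarray,
                     cls: int) -> tuple[int, int, int, int]:
    """Binary (TP, FP, FN, TN) for one class; counts partition the grid."""
    p = pred.values if isinstance(pred, LabelVolume) else np.asarray(pred)
    g = gt.values if isinstance(gt, LabelVolume) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    pp = p == cls
    gg = g == cls
    tp = int(np.sum(pp & gg))
    fp = int(np.sum(pp & ~gg))
    fn = int(np.sum(~pp & gg))
    tn = int(np.sum(~pp & ~gg))
    return tp, fp, fn, tn


def segmentation_metrics(counts, smooth: float = SMOOTH) -> dict:
    """DSC, PPV and SEN from (TP, FP, FN, TN) with symmetric smoothing.

    DSC = (2TP+s)/(2TP+FP+FN+s); PPV = (TP+s)/(TP+FP+s);
    SEN = (TP+s)/(TP+FN+s).  With both masks empty all three equal 1.
    """
    tp, fp, fn, _tn = counts
    if min(tp, fp, fn, _tn) < 0:
        raise ValueError(f"negative confusion counts: {counts}")
    s = smooth
    return {
        "dsc": (2 * tp + s) / (2 * tp + fp + fn + s),
        "ppv": (tp + s) / (tp + fp + s),
        "sen": (tp + s) / (tp + fn + s),
    }


def evaluate_pair(pred: LabelVolume | np.ndarray, gt: LabelVolume | np.ndarray,
                  classes=(1, 2), smooth: float = SMOOTH) -> MetricsResult:
    """Per-class metrics of a predicted label volume against ground truth."""
    res = MetricsResult(smooth=smooth)
    for cls in classes:
        counts = confusion_counts(pred, gt, cls)
        res.counts[cls] = counts
        res.per_class[cls] = segmentation_metrics(counts, smooth)
    return res
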