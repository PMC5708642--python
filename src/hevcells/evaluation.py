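"""Scoring a consensus result against a pixel-level gold standard.

The expert annotation R labels pixels as background / epithelium /
stroma, while the consensus labels v-cells, so R is first transferred to
the v-cell level (majority pixel class per v-cell) giving the v-cell
gold standard G.  The report then holds: the Rand index over v-cell
pairs; precision, recall and F1 computed pixel-wise with epithelium as
the positive class (the two anonymous prediction clusters are mapped
onto epithelium/stroma by maximal pixel overlap first); and the Jaccard
index of the predicted vs gold epithelium pixel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .clustering import Partition
from .errors import FormatError, InsufficientDataError
from .segmentation import VCellMap
from .selection import rand_index

BACKGROUND, EPITHELIUM, STROMA = 0, 1, 2
#: tie priority when a v-cell splits evenly across classes
_CLASS_PRIORITY = (EPITHELIUM, STROMA, BACKGROUND)


@dataclass(frozen=True)
class EvalReport:
    rand_index: float
    precision: float
    recall: float
    f1: float
    jaccard: float

    def as_dict(self) -> dict:
        return asdict(self)


def transfer_gold(pixel_gold: np.ndarray, vcells: VCellMap) -> np.ndarray:
    """Majority-vote transfer of the pixel gold standard onto v-cells.

    Returns the class of each v-cell (index 0 -> id 1).  Exact ties are
    broken by the fixed priority epithelium > stroma > background.
    """
    pixel_gold = np.asarray(pixel_gold)
    if pixel_gold.shape != vcells.labels.shape:
        raise FormatError(
            f"gold standard shape {pixel_gold.shape} != label image {vcells.labels.shape}")
    n = vcells.n_cells
    counts = np.zeros((n + 1, 3), dtype=np.int64)
    for cls in (BACKGROUND, EPITHELIUM, STROMA):
        counts[:, cls] = np.bincount(
            vcells.labels[pixel_gold == cls].ravel(), minlength=n + 1)
    counts = counts[1:]
    best = counts.max(axis=1)
    out = np.empty(n, dtype=np.int64)
    out.fill(BACKGROUND)
    for cls in reversed(_CLASS_PRIORITY):  # later assignments win: priority order
        out[counts[:, cls] == best] = cls
    return out


def _map_clusters_to_classes(pred: np.ndarray, gold: np.ndarray,
                             areas: np.ndarray) -> np.ndarray:
    """Map the two anonymous clusters onto epithelium/stroma by maximal
    pixel overlap; returns per-v-cell class labels."""
    overlap_as_is = areas[(pred == 0) & (gold == EPITHELIUM)].sum() \
        + areas[(pred == 1) & (gold == STROMA)].sum()
    overlap_swap = areas[(pred == 1) & (gold == EPITHELIUM)].sum() \
        + areas[(pred == 0) & (gold == STROMA)].sum()
    if overlap_swap > overlap_as_is:
        return np.where(pred == 1, EPITHELIUM, STROMA)
    return np.where(pred == 0, EPITHELIUM, STROMA)


def evaluate(pred: Partition | np.ndarray, gold_vcells: np.ndarray,
             vcells: VCellMap) -> EvalReport:
    """Score a 2-cluster v-cell partition against the v-cell gold standard."""
    labels = pred.labels if isinstance(pred, Partition) else np.asarray(pred)
    gold_vcells = np.asarray(gold_vcells)
    if len(labels) != len(gold_vcells) or len(labels) != vcells.n_cells:
        raise InsufficientDataError(
            "prediction, gold standard and v-cell map disagree on the number of v-cells")
    areas = vcells.areas()
    keep = gold_vcells != BACKGROUND  # clustering operates on tissue only
    if not keep.any():
        raise InsufficientDataError("gold standard labels every v-cell as background")
    ri = rand_index(labels[keep], gold_vcells[keep])

    mapped = _map_clusters_to_classes(labels, gold_vcells, areas)
    a, m, g = areas[keep], mapped[keep], gold_vcells[keep]
    tp = int(a[(m == EPITHELIUM) & (g == EPITHELIUM)].sum())
    fp = int(a[(m == EPITHELIUM) & (g != EPITHELIUM)].sum())
    fn = int(a[(m != EPITHELIUM) & (g == EPITHELIUM)].sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return EvalReport(ri, precision, recall, f1, jaccard)
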