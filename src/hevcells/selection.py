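"""Diversity-based ensemble selection via the average Rand index.

An ensemble of near-duplicate partitions gains nothing from consensus;
an ensemble polluted with erratic ones harms it.  Each member's mean
Rand index against the rest of the original ensemble is therefore
required to fall inside a moderate-diversity band [D1, D2] (defaults
0.5 and 0.9).  Rejected stochastic members are re-run with fresh seeds
until a compliant solution appears or the attempt budget is spent;
deterministic configurations are removed without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.metrics.cluster import pair_confusion_matrix

from .clustering import Ensemble, Partition
from .errors import EmptyEnsembleError, InsufficientDataError


@dataclass(frozen=True)
class SelectionConfig:
    d1: float = 0.5
    d2: float = 0.9
    max_replacement_attempts: int = 5

    def __post_init__(self):
        if not 0 <= self.d1 < self.d2 <= 1:
            raise InsufficientDataError(
                f"need 0 <= D1 < D2 <= 1, got D1={self.d1}, D2={self.d2}")


def rand_index(li: Partition | np.ndarray, lj: Partition | np.ndarray) -> float:
    """Rand index: the fraction of object pairs on which two partitions agree.

    RI = (TP + TN) / (TP + FP + TN + FN) over all n(n-1)/2 pairs, where
    TP/TN count pairs grouped together/apart under both partitions.
    Invariant under label permutation of either argument.
    """
    a = li.labels if isinstance(li, Partition) else np.asarray(li)
    b = lj.labels if isinstance(lj, Partition) else np.asarray(lj)
    if len(a) != len(b):
        raise InsufficientDataError(f"partition sizes differ: {len(a)} vs {len(b)}")
    # pair_confusion_matrix counts ordered pairs: [[2TN, 2FN], [2FP, 2TP]]
    m = pair_confusion_matrix(a, b)
    total = m.sum()
    if total == 0:  # n < 2: no pairs; identical by convention
        return 1.0
    return float((m[0, 0] + m[1, 1]) / total)


def ensemble_similarity(index: int, ensemble: Ensemble) -> float:
    """Mean Rand index of member ``index`` against every other member."""
    if len(ensemble) < 2:
        raise EmptyEnsembleError("similarity needs an ensemble of >= 2 partitions")
    others = [rand_index(ensemble[index], p)
              for j, p in enumerate(ensemble) if j != index]
    return float(np.mean(others))


def similarity_profile(ensemble: Ensemble) -> np.ndarray:
    """ensemble_similarity of every member, computed from one RI matrix."""
    c = len(ensemble)
    if c < 2:
        raise EmptyEnsembleError("similarity needs an ensemble of >= 2 partitions")
    ri = np.ones((c, c))
    for i in range(c):
        for j in range(i + 1, c):
            ri[i, j] = ri[j, i] = rand_index(ensemble[i], ensemble[j])
    return (ri.sum(axis=1) - 1.0) / (c - 1)


def _similarity_vs(partition: Partition, ensemble: Ensemble) -> float:
    """Mean RI of an external partition against all members of ``ensemble``."""
    return float(np.mean([rand_index(partition, p) for p in ensemble]))


def select_ensemble(
    ensemble: Ensemble,
    config: SelectionConfig = SelectionConfig(),
    regenerate: Callable[[Partition, int], Partition | None] | None = None,
):
    """Prune the ensemble to its moderate-diversity subset.

    Members whose mean RI against the *original* ensemble lies in
    [D1, D2] are kept.  Each rejected member is replaced by re-running
    its algorithm with fresh seeds (via ``regenerate(member, attempt)``)
    until the replacement's similarity against the original ensemble
    falls in the band; members that cannot be replaced are dropped.

    Returns ``(selected_ensemble, report)`` where the report lists each
    member's similarity and kept/replaced/removed status.
    """
    sims = similarity_profile(ensemble)
    selected, report = [], []
    for i, (part, sim) in enumerate(zip(ensemble, sims)):
        entry = {"index": i, "algorithm": part.algorithm,
                 "similarity": float(sim), "status": "kept"}
        if config.d1 <= sim <= config.d2:
            selected.append(part)
        else:
            entry["status"] = "removed"
            if regenerate is not None:
                for attempt in range(config.max_replacement_attempts):
                    candidate = regenerate(part, attempt)
                    if candidate is None:
                        break  # deterministic algorithm: nothing new to offer
                    cand_sim = _similarity_vs(candidate, ensemble)
                    if config.d1 <= cand_sim <= config.d2:
                        selected.append(candidate)
                        entry["status"] = "replaced"
                        entry["replacement_similarity"] = float(cand_sim)
                        break
        report.append(entry)
    if not selected:
        raise EmptyEnsembleError("every partition was rejected by the diversity band")
    return Ensemble(selected), report
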