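"""Consensus functions: evidence accumulation and image-overlap voting.

Evidence accumulation (EAC) counts, for every pair of v-cells, the
fraction of ensemble members that group them together (co-association
matrix) and extracts the consensus partition by hierarchical clustering
of that matrix — robust but O(n^2) in the number of v-cells.

The voting consensus instead aligns the arbitrary cluster labels across
members by rendering each cluster as a pixel set in the segmented image
and matching clusters of maximal Jaccard overlap against a reference
member; aligned labels are then combined by per-object majority vote.
With two classes the alignment needs only one swap decision per member,
so the whole consensus is linear in n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .clustering import Ensemble, Partition
from .errors import EmptyEnsembleError, InsufficientDataError
from .segmentation import VCellMap
from .selection import similarity_profile


@dataclass
class ConsensusResult:
    partition: Partition
    method: str


def coassociation(ensemble: Ensemble) -> np.ndarray:
    """Co-association matrix M, M_ij = (#members grouping i,j together) / C."""
    if len(ensemble) == 0:
        raise EmptyEnsembleError("cannot build a co-association matrix from nothing")
    lm = ensemble.labels_matrix()  # (n, C)
    n, c = lm.shape
    m = np.zeros((n, n))
    for j in range(c):
        col = lm[:, j]
        m += (col[:, None] == col[None, :])
    return m / c


def eac_consensus(m: np.ndarray, k: int = 2, linkage: str = "average") -> ConsensusResult:
    """Cut an average-linkage dendrogram of 1 - M into k clusters."""
    m = np.asarray(m, dtype=float)
    if m.shape[0] < k:
        raise InsufficientDataError(f"co-association matrix of size {m.shape[0]} < k={k}")
    dist = 1.0 - m
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage=linkage)
    labels = model.fit_predict(dist)
    return ConsensusResult(Partition(labels, "eac", {"linkage": linkage}), "eac")


def jaccard_cluster_overlap(
    members_a: np.ndarray,
    members_b: np.ndarray,
    vcells: VCellMap,
    rasterise: bool = False,
) -> float:
    """Jaccard index of the pixel sets covered by two clusters of v-cells.

    ``members_a``/``members_b`` are boolean vectors over the v-cell ids
    (index 0 -> id 1).  By default the overlap is computed by
    area-weighted set arithmetic over the v-cell areas, which is exactly
    the pixel-set Jaccard because v-cells are disjoint; ``rasterise``
    computes it literally on rendered binary images (conformance path).
    """
    a = np.asarray(members_a, dtype=bool)
    b = np.asarray(members_b, dtype=bool)
    if rasterise:
        ids = vcells.ids
        img_a = np.isin(vcells.labels, ids[a])
        img_b = np.isin(vcells.labels, ids[b])
        union = (img_a | img_b).sum()
        return float((img_a & img_b).sum() / union) if union else 0.0
    areas = vcells.areas()
    inter = areas[a & b].sum()
    union = areas[a | b].sum()
    return float(inter / union) if union else 0.0


def align_labels(
    ensemble: Ensemble,
    vcells: VCellMap,
    reference_index: int | None = None,
    original: Ensemble | None = None,
) -> tuple[Ensemble, int]:
    """Match the binary cluster labels of every member to a reference member.

    The reference defaults to the member with the highest mean Rand
    index against ``original`` (or the ensemble itself); it is never
    modified.  For each other member, the cluster with maximal Jaccard
    pixel overlap against the reference's cluster-0 keeps/receives
    label 0 — with two clusters this is a single swap decision.
    """
    if len(ensemble) == 0:
        raise EmptyEnsembleError("nothing to align")
    if reference_index is None:
        pool = original if original is not None else ensemble
        sims = [np.mean([_ri(p, q) for q in pool]) for p in ensemble]
        reference_index = int(np.argmax(sims))
    ref = ensemble[reference_index]
    ref0 = ref.labels == 0
    aligned = []
    for idx, part in enumerate(ensemble):
        if idx == reference_index:
            aligned.append(part)
            continue
        j_same = jaccard_cluster_overlap(ref0, part.labels == 0, vcells)
        j_swap = jaccard_cluster_overlap(ref0, part.labels == 1, vcells)
        if j_swap > j_same:
            aligned.append(Partition(1 - part.labels, part.algorithm,
                                     {**part.params, "labels_swapped": True},
                                     part.seed))
        else:
            aligned.append(part)
    return Ensemble(aligned), reference_index


def _ri(p: Partition, q: Partition) -> float:
    from .selection import rand_index
    return rand_index(p, q)


def voting_consensus(
    ensemble: Ensemble,
    vcells: VCellMap,
    original: Ensemble | None = None,
) -> ConsensusResult:
    """Majority vote over Jaccard-aligned member labels.

    Vote ties on a v-cell take the label given by the member with the
    highest mean Rand index against the original ensemble (residual
    ties: the lower cluster label).  No pairwise n x n structure is
    built, so the cost is linear in the number of v-cells.
    """
    if len(ensemble) == 0:
        raise EmptyEnsembleError("cannot vote with an empty ensemble")
    aligned, _ = align_labels(ensemble, vcells, original=original)
    lm = aligned.labels_matrix()  # (n, C), labels in {0, 1}
    votes1 = lm.sum(axis=1)
    c = lm.shape[1]
    labels = np.where(2 * votes1 > c, 1, 0)
    ties = 2 * votes1 == c
    if ties.any():
        pool = original if original is not None else aligned
        if len(pool) >= 2:
            sims = [np.mean([_ri(p, q) for q in pool if q is not p]) for p in aligned]
        else:
            sims = [1.0] * len(aligned)
        sims = np.asarray(sims)
        best = np.flatnonzero(sims == sims.max())
        # residual tie (equal votes and equal similarity): lower label wins
        labels[ties] = lm[np.ix_(ties.nonzero()[0], best)].min(axis=1)
    return ConsensusResult(Partition(labels, "voting", {}), "voting")


def consensus_from_ensemble(
    ensemble: Ensemble,
    vcells: VCellMap,
    method: str = "voting",
    original: Ensemble | None = None,
) -> ConsensusResult:
    if method == "eac":
        return eac_consensus(coassociation(ensemble))
    if method == "voting":
        return voting_consensus(ensemble, vcells, original=original)
    raise InsufficientDataError(f"unknown consensus method {method!r}")


def render_consensus(
    result: ConsensusResult,
    vcells: VCellMap,
    class_colours=((255, 0, 255), (0, 170, 0)),
) -> np.ndarray:
    """RGB rendering of the consensus: magenta/green classes, white
    background, black v-cell boundaries."""
    from skimage.segmentation import find_boundaries

    labels = vcells.labels
    out = np.full(labels.shape + (3,), 255, dtype=np.uint8)
    lut = np.zeros(vcells.n_cells + 1, dtype=int)
    lut[1:] = result.partition.labels
    for cls, colour in enumerate(class_colours):
        mask = (labels > 0) & (lut[labels] == cls)
        out[mask] = colour
    out[find_boundaries(labels, mode="outer")] = (0, 0, 0)
    return out
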