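import time

import numpy as np
import pytest

from hevcells.clustering import Ensemble, Partition
from hevcells.consensus import (align_labels, coassociation, eac_consensus,
                                jaccard_cluster_overlap, render_consensus,
                                voting_consensus)
from hevcells.errors import EmptyEnsembleError
from hevcells.selection import rand_index, similarity_profile
from hevcells.synthetic import generate_planted_features

from conftest import make_flat_vcells
from oracles import brute_set_jaccard


def P(labels, algo="kmeans"):
    return Partition(np.asarray(labels), algo)


class TestCoassociation:
    def test_identical_partitions_give_block_matrix(self):
        labels = np.array([0, 0, 1, 1, 1])
        m = coassociation(Ensemble([P(labels)] * 4))
        expect = (labels[:, None] == labels[None, :]).astype(float)
        assert np.array_equal(m, expect)

    def test_fractional_counts(self):
        e = Ensemble([P([0, 0, 1]), P([0, 0, 1]), P([0, 1, 1]), P([0, 1, 0])])
        m = coassociation(e)
        assert m[0, 1] == pytest.approx(2 / 4)   # together in 2 of 4
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)


class TestEAC:
    def test_recovers_partition_from_identical_members(self):
        labels = np.array([0, 0, 0, 1, 1, 0, 1])
        res = eac_consensus(coassociation(Ensemble([P(labels)] * 5)))
        assert rand_index(res.partition.labels, labels) == 1.0

    def test_exact_blocks(self):
        m = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1.0]])
        res = eac_consensus(m)
        l = res.partition.labels
        assert l[0] == l[1] != l[2]

    def test_outvotes_noisy_members(self):
        truth = np.arange(40) % 2
        rng = np.random.default_rng(1)
        members = [P(truth) for _ in range(6)]
        members += [P(rng.integers(0, 2, 40)) for _ in range(3)]
        res = eac_consensus(coassociation(Ensemble(members)))
        assert rand_index(res.partition.labels, truth) >= 0.95


class TestJaccardOverlap:
    def test_identical_and_disjoint(self):
        vc = make_flat_vcells(4, areas=[10, 10, 10, 30])
        a = np.array([True, True, False, False])
        b = np.array([False, False, True, True])
        assert jaccard_cluster_overlap(a, a, vc) == 1.0
        assert jaccard_cluster_overlap(a, b, vc) == 0.0

    def test_area_weighted_example(self):
        # c covers areas {10,10}; c' covers {10,30}, sharing one area-10 cell
        vc = make_flat_vcells(3, areas=[10, 10, 30])
        c = np.array([True, True, False])
        cp = np.array([False, True, True])
        assert jaccard_cluster_overlap(c, cp, vc) == pytest.approx(10 / 50)

    def test_both_empty_defined_zero(self):
        vc = make_flat_vcells(3)
        z = np.zeros(3, dtype=bool)
        assert jaccard_cluster_overlap(z, z, vc) == 0.0

    def test_area_arithmetic_equals_rasterisation(self, rng):
        areas = rng.integers(1, 20, size=12)
        vc = make_flat_vcells(12, areas=areas)
        for _ in range(20):
            a = rng.random(12) < 0.5
            b = rng.random(12) < 0.5
            fast = jaccard_cluster_overlap(a, b, vc)
            slow = jaccard_cluster_overlap(a, b, vc, rasterise=True)
            oracle = brute_set_jaccard(np.flatnonzero(a), np.flatnonzero(b), areas)
            assert fast == pytest.approx(slow)
            assert fast == pytest.approx(oracle)


class TestAlignment:
    def test_swapped_labels_restored(self):
        vc = make_flat_vcells(6)
        ref = P([0, 0, 1, 1, 0, 1])
        swapped = P(1 - ref.labels)
        aligned, ridx = align_labels(Ensemble([ref, swapped]), vc, reference_index=0)
        assert ridx == 0
        assert np.array_equal(aligned[1].labels, ref.labels)
        assert np.array_equal(aligned[0].labels, ref.labels)  # reference untouched

    def test_identity_unchanged(self):
        vc = make_flat_vcells(5)
        ref = P([0, 1, 0, 1, 1])
        aligned, _ = align_labels(Ensemble([ref, P(ref.labels.copy())]), vc,
                                  reference_index=0)
        assert np.array_equal(aligned[1].labels, ref.labels)

    def test_matches_brute_force_over_both_mappings(self, rng):
        # alignment must pick whichever of the 2 label mappings maximises
        # the per-cluster Jaccard overlap with the reference
        areas = rng.integers(1, 15, size=20)
        vc = make_flat_vcells(20, areas=areas)
        ref = P(rng.integers(0, 2, 20))
        for _ in range(10):
            other = P(rng.integers(0, 2, 20))
            aligned, _ = align_labels(Ensemble([ref, other]), vc, reference_index=0)
            ji_keep = jaccard_cluster_overlap(ref.labels == 0, other.labels == 0, vc)
            ji_swap = jaccard_cluster_overlap(ref.labels == 0, other.labels == 1, vc)
            expect = 1 - other.labels if ji_swap > ji_keep else other.labels
            assert np.array_equal(aligned[1].labels, expect)


class TestVoting:
    def test_unanimous(self):
        vc = make_flat_vcells(6)
        labels = np.array([0, 1, 1, 0, 0, 1])
        res = voting_consensus(Ensemble([P(labels)] * 3), vc)
        assert rand_index(res.partition.labels, labels) == 1.0

    def test_majority_outvotes_dissenter(self):
        vc = make_flat_vcells(5)
        base = np.array([0, 0, 1, 1, 1])
        dissent = base.copy()
        dissent[0] = 1
        res = voting_consensus(Ensemble([P(base), P(base), P(dissent)]), vc)
        assert np.array_equal(res.partition.labels, base)

    def test_tie_broken_by_ensemble_similarity(self):
        # two members disagree on the last object; the tied vote must follow
        # the member with the higher mean RI against the original ensemble
        vc = make_flat_vcells(6)
        a = np.array([0, 0, 0, 1, 1, 0])
        b = np.array([0, 0, 0, 1, 1, 1])
        original = Ensemble([P(a), P(b), P(a.copy())])  # 'a' is the majority trend
        sims = similarity_profile(original)
        assert sims[0] > sims[1]
        res = voting_consensus(Ensemble([P(a), P(b)]), vc, original=original)
        assert res.partition.labels[5] == a[5]

    def test_label_permutation_invariance(self, rng):
        vc = make_flat_vcells(30)
        truth = rng.integers(0, 2, 30)
        members = [P((truth + (rng.random(30) < 0.1)) % 2) for _ in range(5)]
        base = voting_consensus(Ensemble(members), vc)
        flipped = [P(1 - m.labels) if i % 2 else m for i, m in enumerate(members)]
        perm = voting_consensus(Ensemble(flipped), vc)
        assert rand_index(base.partition.labels, perm.partition.labels) == 1.0

    def test_empty_ensemble_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            voting_consensus(Ensemble([]), make_flat_vcells(3))

    def test_linear_scaling_no_pairwise_work(self):
        # voting builds no n x n structure: n = 4000 must cost little more
        # than 4x the n = 1000 run (O(n^2) would cost ~16x)
        rng = np.random.default_rng(0)

        def run(n):
            vc = make_flat_vcells(n)
            truth = rng.integers(0, 2, n)
            members = [P((truth + (rng.random(n) < 0.1)) % 2) for _ in range(7)]
            ens = Ensemble(members)
            t0 = time.perf_counter()
            voting_consensus(ens, vc, original=ens)
            return time.perf_counter() - t0

        run(1000)  # warm-up
        t1, t4 = min(run(1000) for _ in range(3)), min(run(4000) for _ in range(3))
        assert t4 < 8 * max(t1, 1e-3)


class TestRendering:
    def test_consensus_rendering_colours(self):
        labels = np.zeros((10, 12), dtype=np.int32)
        labels[2:8, 1:5] = 1
        labels[2:8, 7:11] = 2
        from hevcells.segmentation import VCellMap
        vc = VCellMap(labels, labels.copy())
        res = voting_consensus(Ensemble([P([0, 1]), P([0, 1]), P([0, 1])]), vc)
        img = render_consensus(res, vc)
        assert img.shape == (10, 12, 3)
        assert (img == 255).all(axis=2).any()          # white background
        assert (img == (0, 0, 0)).all(axis=2).any()    # black boundaries
        interior = img[4, 2], img[4, 9]
        assert tuple(interior[0]) != tuple(interior[1])  # two class colours
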