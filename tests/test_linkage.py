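"""Linkage: filters, pairwise r, grouping, bins, ordering, map functions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_genotype_matrix
from sppmap import linkage, simulate
from sppmap.linkage import (
    RecPairs,
    apparent_to_gametic,
    build_bins,
    build_linkage_map,
    classify_bin_matrix,
    count_objective,
    filter_markers,
    group_markers,
    map_distance,
    map_positions,
    order_markers,
    pairwise_r,
    rescue_distorted,
)

MISSING = -1


class TestFilterMarkers:
    def test_missing_threshold_boundary(self):
        g = np.zeros((2, 213), dtype=np.int8)
        g[:, :100] = 1
        g[0, :26] = MISSING  # 26 missing > 25 -> excluded
        g[1, :25] = MISSING  # exactly 25 -> kept
        gm = make_genotype_matrix(g)
        kept, skewed, missing = filter_markers(gm, max_missing_rils=25)
        assert 0 in missing and 1 in kept

    def test_allele_ratio_boundary(self):
        g = np.concatenate([np.zeros(30), np.ones(180)]).astype(np.int8)
        gm = make_genotype_matrix(np.vstack([g]))
        kept, skewed, missing = filter_markers(gm, max_missing_rils=200)
        # 30/180 = 0.1667 <= 0.2 -> skewed
        assert 0 in skewed

    def test_balanced_complete_locus_kept(self):
        g = np.concatenate([np.zeros(100), np.ones(100)]).astype(np.int8)
        gm = make_genotype_matrix(np.vstack([g]))
        kept, _, _ = filter_markers(gm)
        assert 0 in kept

    def test_default_missing_threshold_scales_with_population(self):
        g = np.zeros((1, 213), dtype=np.int8)
        g[0, 100:] = 1
        g[0, :26] = MISSING
        gm = make_genotype_matrix(g)
        _, _, missing = filter_markers(gm)  # default: 12% of 213 = 25
        assert 0 in missing


class TestPairwiseR:
    def test_examples(self):
        g = np.array([
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
            [0, 1, 0, 1],
        ], dtype=np.int8)
        pairs = pairwise_r(make_genotype_matrix(g))
        assert pairs.r_hat[0, 1] == 0.0          # identical
        assert pairs.r_hat[0, 2] == 1.0          # complementary
        assert pairs.r_hat[0, 3] == pytest.approx(0.5)  # AABB vs ABAB
        np.testing.assert_allclose(pairs.r_hat, pairs.r_hat.T)

    def test_pairwise_complete_counting(self):
        g = np.array([
            [0, 0, 1, MISSING],
            [0, 1, 1, 1],
        ], dtype=np.int8)
        pairs = pairwise_r(make_genotype_matrix(g))
        assert pairs.n_informative[0, 1] == 3
        assert pairs.n_recombinant[0, 1] == 1

    def test_triangle_inequality_on_complete_data(self):
        rng = np.random.default_rng(4)
        g = (rng.random((10, 60)) < 0.5).astype(np.int8)
        pairs = pairwise_r(make_genotype_matrix(g))
        n = pairs.n_recombinant
        for a in range(10):
            for b in range(10):
                for c in range(10):
                    assert n[a, c] <= n[a, b] + n[b, c]


class TestGrouping:
    def test_chromosome_membership_recovered(self, truth_matrix_map):
        # every group is chromosome-pure, and the two largest groups
        # absorb nearly all loci (sparse coverage can split off a
        # fragment at a large inter-locus gap)
        cfg, truth, gm, lmap, pairs = truth_matrix_map
        assert len(lmap.groups) >= 2
        for g in lmap.groups:
            uids = gm.loci.loc[g.loci, "unigene_id"].to_numpy()
            chroms = truth.unigene_positions.loc[uids, "chrom"].nunique()
            assert chroms == 1
        sizes = sorted((len(g.loci) for g in lmap.groups), reverse=True)
        assert sum(sizes[:2]) >= 0.85 * gm.n_loci

    def test_r_max_zero_degenerates_to_bins(self):
        g = np.array([
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [0, 1, 0, 1],
        ], dtype=np.int8)
        pairs = pairwise_r(make_genotype_matrix(g))
        groups, _ = group_markers(pairs, r_max=0.0, min_support=2)
        sets = {frozenset(gr.tolist()) for gr in groups}
        assert frozenset([0, 1]) in sets
        assert frozenset([2]) in sets

    def test_single_chromosome_single_group(self):
        cfg = simulate.SimConfig(n_rils=40, n_chromosomes=1,
                                 chrom_lengths=(80.0,), n_unigenes=60,
                                 seed=13)
        truth = simulate.simulate_pedigree(cfg)
        m = truth.unigene_genotype_matrix().astype(np.int8)
        m[m == 2] = MISSING
        gm = make_genotype_matrix(m)
        groups, _ = group_markers(pairwise_r(gm), min_support=30)
        big = [g for g in groups if len(g) > 1]
        assert len(big) == 1 and len(big[0]) >= 0.95 * gm.n_loci


def _pairs_from_matrix(M, n_inf=100):
    M = np.asarray(M, dtype=float)
    M = np.where(np.isnan(M), 0.0, M)
    M = np.maximum(M, M.T)
    np.fill_diagonal(M, 0.0)
    n = M.shape[0]
    inf = np.full((n, n), n_inf)
    return RecPairs(n_informative=inf,
                    n_recombinant=np.rint(M * n_inf).astype(int),
                    r_hat=M)


#: published pairwise recombination matrix of a six-marker super-bin
SUPER_BIN_36 = np.array([
    [0, 0,      0,      0,      0,      0.0024],
    [0, 0,      0,      0,      0,      0.0024],
    [0, 0,      0,      0,      0,      0.0025],
    [0, 0,      0,      0,      0.0026, 0],
    [0, 0,      0,      0,      0,      0.0026],
    [0, 0,      0,      0,      0,      0],
])


class TestBins:
    def test_super_bin_matrix_classification(self):
        assert classify_bin_matrix(SUPER_BIN_36) == "super-bin"

    def test_all_zero_matrix_is_bin(self):
        assert classify_bin_matrix(np.zeros((4, 4))) == "bin"

    def test_zero_chain_with_internal_recombination_is_super_bin(self):
        M = np.array([[0, 0.0, 0.003],
                      [0.0, 0, 0.0],
                      [0.003, 0.0, 0]])
        assert classify_bin_matrix(M) == "super-bin"

    def test_build_bins_partition_and_classes(self):
        # loci 0-2 pairwise zero (bin); 3 recombines with everything
        M = np.zeros((4, 4))
        M[3, :3] = M[:3, 3] = 0.1
        pairs = _pairs_from_matrix(M, n_inf=50)
        gm = make_genotype_matrix(np.zeros((4, 10), dtype=np.int8))
        bins = build_bins(np.arange(4), pairs, gm)
        counts = bins.counts()
        assert counts == {"bins": 1, "super_bins": 0, "singletons": 1}
        assert sorted(bins.assignments["locus"]) == [0, 1, 2, 3]

    def test_representative_least_missing_tie_by_code(self):
        g = np.zeros((3, 10), dtype=np.int8)
        g[0, 0] = MISSING  # locus 0 has most missing
        gm = make_genotype_matrix(g)
        pairs = _pairs_from_matrix(np.zeros((3, 3)))
        bins = build_bins(np.arange(3), pairs, gm)
        # loci 1 and 2 tie on missing; code of locus 1 (AAAB) sorts first
        assert bins.representatives[0] == 1

    def test_demo_partition_identity(self, demo_objects):
        lmap = demo_objects["curation"].map_v0
        for g in lmap.groups:
            assert sum(len(m) for m in g.bins.members) == len(g.loci)


class TestOrdering:
    def test_three_markers_brute_force(self):
        M = np.array([[0, 0.01, 0.02],
                      [0.01, 0, 0.01],
                      [0.02, 0.01, 0]])
        pairs = _pairs_from_matrix(M, n_inf=1000)
        order = list(order_markers(np.arange(3), pairs))
        assert order[1] == 1  # B must sit between A and C

    def test_two_markers_any_order(self):
        pairs = _pairs_from_matrix(np.array([[0, 0.1], [0.1, 0]]))
        order = order_markers(np.arange(2), pairs)
        assert sorted(order) == [0, 1]

    def test_disconnected_representatives_error(self):
        g = np.array([[0, 0, MISSING, MISSING],
                      [MISSING, MISSING, 0, 0]], dtype=np.int8)
        pairs = pairwise_r(make_genotype_matrix(g))
        with pytest.raises(ValueError, match="not mutually observed"):
            order_markers(np.arange(2), pairs)

    def test_local_search_never_worse_than_greedy(self, truth_matrix_map):
        cfg, truth, gm, lmap, pairs = truth_matrix_map
        for g in lmap.groups:
            final = count_objective(list(g.order), pairs.n_recombinant)
            greedy = linkage._greedy_insertion(
                np.array(list(g.bins.representatives)), pairs.n_recombinant)
            assert final <= count_objective(greedy, pairs.n_recombinant)


class TestMapFunctions:
    def test_closed_forms(self):
        assert map_distance(0.0, "kosambi") == 0.0
        assert map_distance(0.25, "kosambi") == pytest.approx(27.465, abs=1e-3)
        assert map_distance(0.25, "haldane") == pytest.approx(34.657, abs=1e-3)

    @given(st.floats(1e-6, 0.499))
    def test_haldane_dominates_kosambi(self, r):
        assert map_distance(r, "haldane") >= map_distance(r, "kosambi")

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            map_distance(0.5)
        with pytest.raises(ValueError):
            map_distance(-0.1)

    def test_selfing_correction_inverts_fixed_point(self):
        r = np.array([0.0, 0.05, 0.2])
        R = 2 * r / (1 + 2 * r)
        np.testing.assert_allclose(apparent_to_gametic(R), r, atol=1e-12)

    def test_haldane_map_longer_than_kosambi(self, truth_matrix_map):
        cfg, truth, gm, lmap, pairs = truth_matrix_map
        for g in lmap.groups:
            k = map_positions(g.order, pairs, "kosambi")[-1]
            h = map_positions(g.order, pairs, "haldane")[-1]
            assert h >= k

    def test_positions_non_decreasing(self, truth_matrix_map):
        *_, lmap, pairs = truth_matrix_map
        for g in lmap.groups:
            assert (np.diff(g.positions) >= 0).all()


class TestRescue:
    def _distorted_setup(self):
        """One chromosome; a central block of loci is skewed and excluded,
        leaving a gap in the initial map."""
        cfg = simulate.SimConfig(n_rils=60, n_chromosomes=1,
                                 chrom_lengths=(100.0,), n_unigenes=80,
                                 seed=17)
        truth = simulate.simulate_pedigree(cfg)
        m = truth.unigene_genotype_matrix().astype(np.int8)
        m[m == 2] = MISSING
        gm = make_genotype_matrix(m)
        cm = truth.unigene_positions["cm"].to_numpy()
        central = np.flatnonzero((cm > 40) & (cm < 70))
        keep = np.flatnonzero((cm <= 40) | (cm >= 70))
        return truth, gm, keep, central

    def test_no_linked_skewed_loci_leaves_map_unchanged(self,
                                                        truth_matrix_map):
        *_, gm, lmap, pairs = truth_matrix_map
        out, report = rescue_distorted(gm, pairs, lmap,
                                       skewed=np.array([], dtype=int))
        assert out.total_length == pytest.approx(lmap.total_length)
        assert (report["n_rescued"] == 0).all()

    def test_rescue_fills_gap(self):
        truth, gm, keep, central = self._distorted_setup()
        pairs = pairwise_r(gm)
        groups = [keep]
        lmap, _ = build_linkage_map(gm, pairs=pairs, groups=groups,
                                    labels=["LG1"], min_support=30)
        gap_before = lmap.groups[0].max_gap()
        assert gap_before > 20.0
        out, report = rescue_distorted(gm, pairs, lmap, skewed=central,
                                       gap_threshold=20.0, min_support=30)
        assert report.loc[0, "n_rescued"] > 0
        assert out.groups[0].max_gap() < gap_before

    def test_rescued_loci_near_true_positions(self):
        truth, gm, keep, central = self._distorted_setup()
        pairs = pairwise_r(gm)
        lmap, _ = build_linkage_map(gm, pairs=pairs, groups=[keep],
                                    labels=["LG1"], min_support=30)
        out, _ = rescue_distorted(gm, pairs, lmap, skewed=central,
                                  gap_threshold=20.0, min_support=30)
        g = out.groups[0]
        uids = gm.loci.loc[g.order, "unigene_id"].to_numpy()
        true_cm = truth.unigene_positions.loc[uids, "cm"].to_numpy()
        tau = abs(__import__("scipy.stats", fromlist=["kendalltau"])
                  .kendalltau(g.positions, true_cm).statistic)
        assert tau >= 0.9
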