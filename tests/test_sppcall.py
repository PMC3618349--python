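"""SPP caller: GC-bin statistics, SPPdev, gap search, calls, ranges, QC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sppmap import simulate, sppcall
from sppmap.simulate import IntensityDataset
from sppmap.sppcall import (
    MISSING,
    WeightCurve,
    assign_gc_bins,
    compute_gcbin_stats,
    detect_gap,
    filter_spps,
    qc_cluster_chips,
    sppdev_at_window,
    summarize_ranges,
    valid_probes,
)


def _dataset(intensities, probes, chips=None):
    intensities = np.asarray(intensities, dtype=float)
    if chips is None:
        chips = pd.DataFrame({
            "chip_id": [f"c{i}" for i in range(intensities.shape[0])],
            "source": "RIL",
            "line": np.arange(intensities.shape[0]),
            "replicate": 1,
        })
    return IntensityDataset(intensities=intensities, chips=chips,
                            probes=probes)


def _probe_table(gc_counts, antigenomic=None, unigene=0):
    n = len(gc_counts)
    if antigenomic is None:
        antigenomic = [False] * n
    centers = []
    c = 13
    for a in antigenomic:
        centers.append(0 if a else c)
        if not a:
            c += 2
    return pd.DataFrame({
        "probe_id": np.arange(n),
        "unigene_id": [(-1 if a else unigene) for a in antigenomic],
        "center_position": centers,
        "strand": ["." if a else "+" for a in antigenomic],
        "gc_count": gc_counts,
        "antigenomic": antigenomic,
    })


class TestGCBins:
    def test_single_and_multiple_bins_partition(self):
        probes = _probe_table([12, 12, 12])
        bins = assign_gc_bins(probes)
        assert set(bins) == {12}
        probes = _probe_table([10, 11, 12, 10])
        bins = assign_gc_bins(probes)
        assert sorted(bins.unique()) == [10, 11, 12]
        assert len(bins) == len(probes)  # exhaustive, disjoint by construction

    def test_reference_is_arithmetic_mean(self):
        probes = _probe_table([12, 12, 12] + [12] * 10,
                              [False] * 3 + [True] * 10)
        X = np.r_[[1.0, 2.0, 3.0], np.full(10, 0.1)][None, :]
        stats = compute_gcbin_stats(_dataset(X, probes))
        assert stats.reference[0, 0] == pytest.approx(2.0)

    def test_background_cutoff_linear_interpolated_90th(self):
        probes = _probe_table([12] + [12] * 10, [False] + [True] * 10)
        X = np.r_[[5.0], np.arange(1.0, 11.0)][None, :]
        stats = compute_gcbin_stats(_dataset(X, probes))
        assert stats.background_cutoff[0, 0] == pytest.approx(9.1)

    def test_uniform_chip_reference_constant(self):
        probes = _probe_table([10] * 3 + [15] * 3 + [10] * 10 + [15] * 10,
                              [False] * 6 + [True] * 20)
        X = np.full((2, 26), 7.0)
        stats = compute_gcbin_stats(_dataset(X, probes))
        np.testing.assert_allclose(stats.reference, 7.0)

    def test_empty_bin_raises_with_bin_name(self):
        probes = _probe_table([12, 12], [False, True])
        with pytest.raises(sppcall.EmptyBinError, match="12"):
            compute_gcbin_stats(_dataset(np.ones((1, 2)), probes))


class TestValidity:
    def test_boundary_equality_is_valid(self):
        probes = _probe_table([12] + [12] * 10, [False] + [True] * 10)
        X = np.r_[[9.1], np.arange(1.0, 11.0)][None, :]
        stats = compute_gcbin_stats(_dataset(X, probes))
        mask = valid_probes(_dataset(X, probes), stats)
        assert mask[0, 0]  # intensity == cutoff stays valid
        X[0, 0] = 9.0999
        mask = valid_probes(_dataset(X, probes), stats)
        assert not mask[0, 0]

    def test_antigenomic_never_valid(self):
        probes = _probe_table([12] + [12] * 10, [False] + [True] * 10)
        X = np.full((1, 11), 100.0)
        stats = compute_gcbin_stats(_dataset(X, probes))
        mask = valid_probes(_dataset(X, probes), stats)
        assert not mask[0, 1:].any()

    def test_default_simulation_mostly_valid(self, small_dataset):
        _, _, data = small_dataset
        stats = compute_gcbin_stats(data)
        mask = valid_probes(data, stats)
        genomic = ~data.probes["antigenomic"].to_numpy()
        assert mask[:, genomic].mean() > 0.95


class TestSPPdev:
    def test_zero_when_intensity_equals_reference(self):
        probes = _probe_table([12] * 5 + [12] * 10,
                              [False] * 5 + [True] * 10)
        X = np.r_[np.full(5, 100.0), np.full(10, 1.0)][None, :]
        stats = compute_gcbin_stats(_dataset(X, probes))
        dev = sppdev_at_window(_dataset(X, probes), stats, WeightCurve(), 0, 13)
        assert dev[0] == pytest.approx(0.0)

    def test_formula_single_probe(self):
        probes = _probe_table([12] + [12] * 10, [False] + [True] * 10)
        X = np.r_[[2000.0], np.full(10, 1.0)][None, :]
        stats = compute_gcbin_stats(_dataset(X, probes))
        # reference = 2000 (only genomic probe); craft a second chip where
        # probe reads 2000 but reference is 1000 via explicit stats override
        stats.reference[0, 0] = 1000.0
        dev = sppdev_at_window(_dataset(X, probes), stats, WeightCurve(), 0, 13)
        assert dev[0] == pytest.approx(0.5)  # |(2000-1000)/2000|

    def test_weighting_favours_central_probe(self):
        # probes at distance 0 and 12 with deviations 0.4 and 0.0:
        # any admissible curve weights d=0 at least as much, so the
        # window SPPdev must exceed the plain midpoint 0.2
        curve = WeightCurve()
        w0, w12 = curve(np.array([0])), curve(np.array([12]))
        dev = (0.4 * w0 + 0.0 * w12) / (w0 + w12)
        assert dev[0] > 0.2

    def test_chip_scaling_invariance(self, small_dataset):
        # SPPdev compares each chip with its own reference, so scaling a
        # whole chip cancels out of |(I - ref)/I|
        _, _, data = small_dataset
        stats = compute_gcbin_stats(data)
        dev1 = sppdev_at_window(data, stats, WeightCurve(), 0, 13)
        scaled = IntensityDataset(intensities=data.intensities * 1.0,
                                  chips=data.chips, probes=data.probes)
        scaled.intensities[3] *= 7.5
        stats2 = compute_gcbin_stats(scaled)
        dev2 = sppdev_at_window(scaled, stats2, WeightCurve(), 0, 13)
        np.testing.assert_allclose(dev1, dev2, rtol=1e-10)


class TestGapSearch:
    def test_first_gap_above_delta(self):
        vals = [0.01, 0.02, 0.03, 0.04, 0.05, 0.40, 0.41]
        split = detect_gap(np.array(vals), 0.2)
        assert split == pytest.approx((0.05 + 0.40) / 2)

    def test_no_gap_cases(self):
        assert detect_gap(np.array([0.3, 0.3, 0.3]), 0.2) is None
        assert detect_gap(np.array([0.1, 0.2, 0.3]), 0.5) is None
        assert detect_gap(np.array([0.1]), 0.01) is None

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2,
                    max_size=30),
           st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    @settings(deadline=None, max_examples=200)
    def test_raising_delta_never_finds_more_gaps(self, vals, d1, d2):
        lo, hi = sorted((d1, d2))
        v = np.array(vals)
        if detect_gap(v, hi) is not None:
            assert detect_gap(v, lo) is not None


class TestGenotypeCalls:
    def _window_setup(self, ril_sides, parent_a_side, parent_b_side):
        """sppdev vector from side booleans (True = high side)."""
        chips = []
        spp = []
        for i, sides in enumerate(ril_sides):
            for rep, s in enumerate(sides):
                chips.append((f"r{i}_{rep}", "RIL", i, rep + 1))
                spp.append(0.9 if s else 0.1)
        for rep, s in enumerate(parent_a_side):
            chips.append((f"pa{rep}", "parentA", -1, rep + 1))
            spp.append(0.9 if s else 0.1)
        for rep, s in enumerate(parent_b_side):
            chips.append((f"pb{rep}", "parentB", -1, rep + 1))
            spp.append(0.9 if s else 0.1)
        chips = pd.DataFrame(chips, columns=["chip_id", "source", "line",
                                             "replicate"])
        return np.array(spp), chips

    def test_consistent_replicates_called(self):
        spp, chips = self._window_setup([(False, False), (True, True)],
                                        (False,) * 4, (True,) * 4)
        calls, reason = sppcall.call_genotypes(spp, 0.5, chips)
        assert reason is None
        assert list(calls) == [0, 1]  # A side = low (parents A low)

    def test_inconsistent_replicates_missing(self):
        spp, chips = self._window_setup([(False, True)],
                                        (False,) * 4, (True,) * 4)
        calls, reason = sppcall.call_genotypes(spp, 0.5, chips)
        assert reason is None
        assert calls[0] == MISSING

    def test_parent_straddle_discards_window(self):
        spp, chips = self._window_setup([(False, False)],
                                        (False, False, True, True),
                                        (True,) * 4)
        _, reason = sppcall.call_genotypes(spp, 0.5, chips)
        assert reason == "parent-straddle"

    def test_parents_same_side_discards_window(self):
        spp, chips = self._window_setup([(False, False)],
                                        (True,) * 4, (True,) * 4)
        _, reason = sppcall.call_genotypes(spp, 0.5, chips)
        assert reason == "parents-same-side"


def _window_calls(positions, discarded, geno):
    table = pd.DataFrame({
        "unigene_id": 0,
        "position": positions,
        "split_value": 0.5,
        "mean_sppdev": 0.4,
        "n_valid_probes": 10.0,
        "discarded": discarded,
        "reason": "",
    })
    return sppcall.WindowCalls(windows=table, geno=np.asarray(geno, np.int8),
                               ril_ids=np.arange(np.asarray(geno).shape[1]))


class TestRanges:
    def test_adjacent_windows_merge(self):
        wc = _window_calls([101, 103, 105], [False] * 3, [[0]] * 3)
        rs = summarize_ranges(wc)
        assert len(rs.table) == 1
        row = rs.table.iloc[0]
        assert (row["start"], row["end"], row["n_windows"]) == (101, 106, 3)

    def test_gap_splits_ranges(self):
        wc = _window_calls([101, 111], [False, False], [[0], [0]])
        rs = summarize_ranges(wc)
        assert len(rs.table) == 2

    def test_majority_consensus_with_missing(self):
        wc = _window_calls([101, 103, 105], [False] * 3,
                           [[0], [0], [MISSING]])
        rs = summarize_ranges(wc)
        assert rs.geno[0, 0] == 0

    def test_tie_becomes_missing(self):
        wc = _window_calls([101, 103], [False, False], [[0], [1]])
        rs = summarize_ranges(wc)
        assert rs.geno[0, 0] == MISSING


class TestFilters:
    def _ranges(self):
        table = pd.DataFrame({
            "unigene_id": [0, 1, 2],
            "start": [1, 1, 1],
            "end": [10, 10, 1],
            "n_windows": [5, 5, 1],
            "mean_sppdev": [0.5, 0.5, 0.5],
            "n_valid_probes": [8.0, 8.0, 8.0],
            "missing_frac": [0.0, 0.30, 0.0],
        })
        geno = np.zeros((3, 10), dtype=np.int8)
        return sppcall.RangeSet(table=table, geno=geno,
                                ril_ids=np.arange(10))

    def test_zero_thresholds_identity(self):
        rs = self._ranges()
        kept, rejected = filter_spps(rs, 0, 1.0, 0, 0)
        assert len(kept.table) == 3 and rejected.empty

    def test_missing_fraction_threshold(self):
        kept, rejected = filter_spps(self._ranges(), max_missing_frac=0.25)
        assert 1 not in kept.table["unigene_id"].values
        assert (rejected["reject_reason"] == "missing").any()

    def test_span_threshold(self):
        kept, _ = filter_spps(self._ranges(), min_span_bp=2)
        assert 2 not in kept.table["unigene_id"].values


class TestQC:
    def test_clean_replicates_unflagged(self, small_dataset):
        _, truth, data = small_dataset
        assert qc_cluster_chips(data) == []

    def test_shuffled_chips_flagged(self):
        cfg = simulate.SimConfig(
            n_rils=15, n_chromosomes=1, chrom_lengths=(80.0,), n_unigenes=60,
            n_bad_chips=2, seed=3)
        truth, data = simulate.simulate_dataset(cfg)
        flagged = qc_cluster_chips(data)
        bad_rils = sorted(
            int(data.chips.set_index("chip_id").loc[c, "line"])
            for c in truth.bad_chips)
        assert sorted(flagged) == bad_rils


class TestEndToEnd:
    def test_no_polymorphism_no_spps(self):
        cfg = simulate.SimConfig(
            n_rils=8, n_chromosomes=1, chrom_lengths=(60.0,), n_unigenes=30,
            signal_depression=0.0, seed=9)
        truth, data = simulate.simulate_dataset(cfg)
        stats = compute_gcbin_stats(data)
        calls = sppcall.call_windows(data, stats, delta=0.2)
        kept, _ = filter_spps(summarize_ranges(calls))
        assert len(kept.table) == 0

    def test_detected_ranges_near_true_sites(self, demo_objects):
        truth = demo_objects["truth"]
        kept = demo_objects["ranges"]
        hits = 0
        for _, r in kept.table.iterrows():
            sites = truth.spp_sites.get(int(r["unigene_id"]),
                                        np.empty(0, dtype=int))
            if len(sites) and ((sites >= r["start"] - 25)
                               & (sites <= r["end"] + 25)).any():
                hits += 1
        assert hits / len(kept.table) >= 0.95
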