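"""Map building: binning, grouping, seriation, assembly."""

import numpy as np
import pandas as pd
import pytest

from conftest import matrix_from_strings
from mapforge._util import round_half_up
from mapforge.linkage import PairwiseEngine
from mapforge.map_builder import (LinkageMap, assemble_map, bin_markers,
                                  build_single_map, exhaustive_order,
                                  group_markers, order_markers)
from mapforge.qc import apply_qc
from mapforge.rilsim import SimConfig, simulate_population, simulate_true_map


class TestBinning:
    def test_identical_columns_share_a_bin(self):
        gm = matrix_from_strings({"a": "AABBAB", "b": "AABBAB", "c": "ABABAB"})
        bins = bin_markers(gm)
        sizes = sorted(len(b.member_markers) for b in bins)
        assert sizes == [1, 2]

    def test_toy_matrix_bins_and_frame_election(self):
        """Markers 1,2,3 duplicated and 7,8 duplicated among 10 -> 7 bins;
        frames elected by minimum missing rate (hand-checked)."""
        rng = np.random.default_rng(1)
        base = rng.choice(["A", "B"], size=(10, 40))
        rows = {f"m{i}": "".join(base[i]) for i in range(10)}
        rows["m2"] = rows["m1"] = rows["m3"]          # duplicates of m3
        rows["m8"] = rows["m7"]
        # give m2 less missing than m1/m3 so it must be the frame
        rows["m1"] = rows["m1"][:-2] + "--"
        rows["m3"] = rows["m3"][:-1] + "-"
        gm = matrix_from_strings(rows)
        # hand check: exhaustive pairwise zero-recombinant relation
        eng = PairwiseEngine(gm)
        zero_pairs = {(gm.marker_ids[i], gm.marker_ids[j])
                      for i in range(10) for j in range(i + 1, 10)
                      if eng.n[i, j] > 0 and eng.k[i, j] == 0}
        assert zero_pairs == {("m1", "m2"), ("m1", "m3"), ("m2", "m3"), ("m7", "m8")}
        bins = bin_markers(gm, eng)
        assert len(bins) == 7
        by_members = {tuple(sorted(b.member_markers)): b for b in bins}
        assert by_members[("m1", "m2", "m3")].frame_marker == "m2"

    def test_all_mutually_recombinant_gives_singletons(self):
        gm = matrix_from_strings({"a": "AABB", "b": "ABAB", "c": "ABBA"})
        bins = bin_markers(gm)
        assert all(len(b.member_markers) == 1 for b in bins)
        assert {b.frame_marker for b in bins} == {"a", "b", "c"}


class TestGrouping:
    def test_two_simulated_chromosomes_give_two_groups(self):
        tm = simulate_true_map({"1A": 60.0, "2A": 60.0}, 15, seed=2)
        gm = simulate_population(tm, SimConfig(n_lines=200, seed=2,
                                               missing_rate=0.0, error_rate=0.0))
        eng = PairwiseEngine(gm)
        groups, unlinked = group_markers(list(gm.marker_ids), eng, lod_threshold=7)
        assert len(groups) == 2 and unlinked == []
        chrom_sets = [{m.split("_")[0] for m in g} for g in groups]
        assert chrom_sets == [{"1A"}, {"2A"}] or chrom_sets == [{"2A"}, {"1A"}]

    def test_threshold_above_all_lods_unlinks_everything(self):
        gm = matrix_from_strings({"a": "AABB", "b": "AABB", "c": "AABB"})
        eng = PairwiseEngine(gm)
        groups, unlinked = group_markers(["a", "b", "c"], eng, lod_threshold=1e6)
        assert groups == [] and sorted(unlinked) == ["a", "b", "c"]

    def test_large_interior_gap_splits_chromosome(self):
        """A 60 cM empty interior at n=100 drops the across-gap LOD below 7
        and fragments the chromosome into multiple linkage groups."""
        pos = np.concatenate([np.linspace(0, 20, 10), np.linspace(80, 100, 10)])
        markers = pd.DataFrame({
            "marker": [f"g{i:02d}" for i in range(20)], "chromosome": "1A",
            "position_cM": pos, "genome": "A", "group": 1})
        from mapforge.rilsim import TrueMap
        tm = TrueMap([("1A", 100.0)], markers)
        gm = simulate_population(tm, SimConfig(n_lines=100, seed=3,
                                               missing_rate=0.0, error_rate=0.0))
        groups, _ = group_markers(list(gm.marker_ids), PairwiseEngine(gm), 7)
        assert len(groups) > 1


class TestOrdering:
    @pytest.mark.parametrize("trial", range(10))
    def test_small_groups_hit_exhaustive_minimum(self, trial):
        rng = np.random.default_rng(100 + trial)
        m = int(rng.integers(4, 9))
        tm = simulate_true_map({"1A": 40.0}, m, seed=int(rng.integers(1 << 30)))
        gm = simulate_population(tm, SimConfig(
            n_lines=120, seed=int(rng.integers(1 << 30)),
            missing_rate=0.05, error_rate=0.01))
        eng = PairwiseEngine(gm)
        got = order_markers(list(gm.marker_ids), eng)
        _, best_cost = exhaustive_order(list(gm.marker_ids), eng)
        D = np.nan_to_num(eng.r_meiotic_matrix(), nan=0.5)
        idx = {mk: i for i, mk in enumerate(gm.marker_ids)}
        sarf = sum(D[idx[a], idx[b]] for a, b in zip(got[:-1], got[1:]))
        assert sarf == pytest.approx(best_cost, abs=1e-12)

    def test_two_markers_trivial(self):
        gm = matrix_from_strings({"b": "AABB", "a": "ABAB"})
        got = order_markers(["b", "a"], PairwiseEngine(gm))
        assert got == ["a", "b"]  # canonical orientation

    def test_fifty_marker_chromosome_recovered(self):
        tm = simulate_true_map({"1A": 100.0}, 50, seed=21)
        gm = simulate_population(tm, SimConfig(n_lines=250, seed=21,
                                               missing_rate=0.05, error_rate=0.0))
        eng = PairwiseEngine(gm)
        got = order_markers(list(gm.marker_ids), eng)
        truth = tm.markers.set_index("marker")["position_cM"]
        from scipy.stats import spearmanr
        rho = spearmanr(np.arange(len(got)), truth.loc[got]).statistic
        assert abs(rho) >= 0.98


class TestAssembly:
    def test_bin_members_colocated_with_frame(self):
        tm = simulate_true_map({"1A": 50.0}, 10, seed=4)
        gm = simulate_population(tm, SimConfig(n_lines=150, seed=4,
                                               missing_rate=0.02, error_rate=0.0))
        lmap, _ = build_single_map(gm)
        pos = lmap.table.set_index("marker")["position_cM"]
        frames = lmap.table[lmap.table["is_frame"]].set_index("bin_id")["position_cM"]
        for _, row in lmap.table.iterrows():
            assert row["position_cM"] == pytest.approx(frames[row["bin_id"]])

    def test_printed_density_example(self):
        # 10,986 markers over 2,156.07 cM -> 5.10 markers/cM at printed precision
        assert round_half_up(10_986 / 2_156.07, 2) == 5.10

    def test_no_anchors_leaves_chromosomes_unassigned(self):
        gm = matrix_from_strings({"a": "AABBAABB", "b": "AABBAABB", "c": "AABBABBB"})
        eng = PairwiseEngine(gm)
        bins = bin_markers(gm, eng)
        frames = [b.frame_marker for b in bins]
        groups, unlinked = group_markers(frames, eng, lod_threshold=0.5)
        lmap = assemble_map(groups, bins, eng, anchors=None, unlinked=unlinked)
        assert lmap.table["chromosome"].isna().all()

    def test_majority_vote_chromosome_assignment(self):
        tm = simulate_true_map({"3B": 60.0}, 12, seed=5)
        gm = simulate_population(tm, SimConfig(n_lines=150, seed=5,
                                               missing_rate=0.0, error_rate=0.0))
        anchors = {m: "3B" for m in gm.marker_ids}
        lmap, _ = build_single_map(gm, anchors=anchors)
        assert (lmap.table["chromosome"] == "3B").all()

    def test_map_tsv_round_trip(self, tmp_path):
        tm = simulate_true_map({"1A": 50.0}, 8, seed=6)
        gm = simulate_population(tm, SimConfig(n_lines=100, seed=6))
        lmap, _ = build_single_map(gm)
        path = tmp_path / "map.tsv"
        lmap.to_tsv(path)
        back = LinkageMap.from_tsv(path)
        assert back.n_markers == lmap.n_markers
        assert back.total_length == pytest.approx(lmap.total_length)


class TestEndToEndRecovery:
    def test_three_chromosome_map_recovers_truth(self):
        """3 chromosomes x 60 markers, n=250, 5% missing, 0.5% error:
        per-chromosome |Spearman| >= 0.95 and length within 25% of truth."""
        from scipy.stats import spearmanr
        tm = simulate_true_map({"1A": 110.0, "2A": 110.0, "3A": 110.0}, 60, seed=31)
        gm = simulate_population(tm, SimConfig(n_lines=250, seed=31,
                                               missing_rate=0.05, error_rate=0.005))
        clean, _ = apply_qc(gm)
        anchors = dict(zip(tm.markers["marker"], tm.markers["chromosome"]))
        lmap, summary = build_single_map(clean, anchors=anchors, seed=31)
        truth = tm.markers.set_index("marker")["position_cM"]
        for chrom in ["1A", "2A", "3A"]:
            sub = lmap.chromosome_table(chrom)
            assert len(sub) > 30
            rho = spearmanr(sub["position_cM"], truth.loc[sub["marker"]]).statistic
            assert abs(rho) >= 0.95
        assert abs(lmap.total_length - 330.0) / 330.0 < 0.25
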