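import itertools

import numpy as np
import pandas as pd
import pytest

from rerepseq.core import RegionSet, TEAnnotation
from rerepseq.rerep import (
    WindowZ,
    annotate_rerep_tes,
    call_regions,
    chromosome_view,
    compare_het_fractions,
    het_fraction,
    log2_ratio,
    pseudocount,
    ranksum_compare,
    score_track,
    te_dna_density,
    window_z,
)
from rerepseq.signal import BinnedSignal, bin_counts
from conftest import placements


class TestPseudocount:
    def test_scaling(self):
        assert pseudocount(10) == 1.0
        assert pseudocount(25.0) == 2.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pseudocount(0)


class TestScoreTrack:
    def test_hand_evaluation(self):
        counts = BinnedSignal(
            values={"chr1": np.array([10, 0])}, bin_width=100
        )
        track = score_track(counts, 68, pseudocount_value=6.8)
        assert track.signal.values["chr1"][0] == pytest.approx(
            (10 + 6.8) / 0.1 / 68
        )

    def test_zero_counts_give_pseudocount_floor(self):
        counts = BinnedSignal(values={"chr1": np.zeros(5)}, bin_width=100)
        track = score_track(counts, 10, pseudocount_value=1.0)
        assert np.allclose(track.signal.values["chr1"], 1.0)
        assert (track.signal.values["chr1"] > 0).all()

    def test_default_pseudocount_is_m_over_ten(self):
        counts = BinnedSignal(values={"chr1": np.zeros(2)}, bin_width=100)
        assert score_track(counts, 40).pseudocount == 4.0


class TestLog2Ratio:
    def _track(self, values, m=10):
        sig = BinnedSignal(
            values={"chr1": np.asarray(values, float)}, bin_width=100
        )
        return score_track(sig, m)

    def test_identity_gives_zero(self):
        t = self._track([5, 10, 20])
        assert np.allclose(log2_ratio(t, t).values["chr1"], 0.0)

    def test_doubled_scores_give_one(self):
        wt = self._track([5, 10, 20])
        mut = self._track([5, 10, 20])
        mut.signal.values["chr1"] = 2 * wt.signal.values["chr1"]
        assert np.allclose(log2_ratio(mut, wt).values["chr1"], 1.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        wt = self._track(rng.integers(0, 50, size=20))
        mut = self._track(rng.integers(0, 50, size=20))
        out = log2_ratio(mut, wt).values["chr1"]
        expected = np.log2(
            mut.signal.values["chr1"] / wt.signal.values["chr1"]
        )
        assert np.allclose(out, expected)
        assert np.isfinite(out).all()

    def test_bin_width_mismatch_rejected(self):
        a = self._track([1, 2])
        b = self._track([1, 2])
        b.signal.bin_width = 200
        with pytest.raises(ValueError):
            log2_ratio(a, b)


class TestWindowZ:
    def test_constant_track_gives_zero_z(self):
        ratio = BinnedSignal(
            values={"chr1": np.full(50, 0.7)}, bin_width=100
        )
        wz = window_z(ratio)
        assert np.allclose(wz.table["z"], 0.0)

    def test_elevated_window_has_max_z(self):
        v = np.zeros(100)
        v[40:50] = 5.0  # exactly one 1-kb window fully elevated
        wz = window_z(BinnedSignal(values={"chr1": v}, bin_width=100))
        top = wz.table.loc[wz.table["z"].idxmax()]
        assert top["start"] == 4000

    def test_standardization_matches_direct_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=200)
        wz = window_z(BinnedSignal(values={"chr1": v}, bin_width=100))
        vals = wz.table["value"].to_numpy()
        expected = (vals - vals.mean()) / vals.std()
        assert np.allclose(wz.table["z"].to_numpy(), expected, atol=1e-12)

    def test_window_values_are_means_of_constituent_bins(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=35)
        wz = window_z(BinnedSignal(values={"chr1": v}, bin_width=100))
        # partial final window dropped: starts 0, 500, ..., 2500
        assert wz.table["start"].tolist() == [0, 500, 1000, 1500, 2000, 2500]
        for row in wz.table.itertuples(index=False):
            assert row.value == pytest.approx(
                v[row.start // 100 : row.end // 100].mean()
            )

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            window_z(BinnedSignal(values={"chr1": np.zeros(5)}, bin_width=100))


class TestCallRegions:
    @staticmethod
    def _wz(rows):
        table = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "z"])
        return WindowZ(table=table, window_bp=1000, step_bp=500)

    def test_gap_within_merge_distance_merges(self):
        wz = self._wz(
            [("chr1", 1000, 2000, 1.0, 3.0), ("chr1", 2400, 3000, 1.0, 3.0)]
        )
        regions = call_regions(wz)
        assert regions.table[["start", "end"]].to_numpy().tolist() == [
            [1000, 3000]
        ]

    def test_gap_beyond_merge_distance_stays_split(self):
        wz = self._wz(
            [("chr1", 0, 1000, 1.0, 3.0), ("chr1", 2000, 3000, 1.0, 3.0)]
        )
        assert len(call_regions(wz)) == 2

    def test_no_passing_windows(self):
        wz = self._wz([("chr1", 0, 1000, 0.0, 0.5)])
        assert len(call_regions(wz)) == 0

    def test_order_invariant_and_idempotent_merge(self):
        rows = [
            ("chr1", 5000, 6000, 1.0, 3.0),
            ("chr1", 0, 1000, 1.0, 3.0),
            ("chr1", 800, 1800, 1.0, 3.0),
        ]
        a = call_regions(self._wz(rows))
        b = call_regions(self._wz(rows[::-1]))
        assert a.table.equals(b.table)
        assert a.merge(gap=500).table.equals(a.table)


class TestAnnotateRerepTes:
    def test_one_bp_overlap_included(self, simple_tes):
        regions = RegionSet.from_tuples([("chr1", 199, 300)])
        assert "TE1" in annotate_rerep_tes(regions, simple_tes)

    def test_touching_excluded(self, simple_tes):
        regions = RegionSet.from_tuples([("chr1", 200, 300)])
        assert "TE1" not in annotate_rerep_tes(regions, simple_tes)

    def test_no_regions_empty_set(self, simple_tes):
        assert annotate_rerep_tes(
            RegionSet.from_tuples([]), simple_tes
        ) == set()

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(7)
        n = 1000
        starts = rng.integers(0, 100_000, size=n)
        regions = RegionSet.from_tuples(
            [
                ("chr1", int(s), int(s + rng.integers(1, 500)))
                for s in starts
            ]
        )
        te_starts = rng.integers(0, 100_000, size=n)
        tes = TEAnnotation(
            pd.DataFrame(
                {
                    "te_id": [f"T{i}" for i in range(n)],
                    "chrom": "chr1",
                    "start": te_starts,
                    "end": te_starts + rng.integers(1, 500, size=n),
                    "superfamily": "LTR/Gypsy",
                }
            )
        )
        fast = annotate_rerep_tes(regions, tes)
        slow = set()
        for te in tes.table.itertuples(index=False):
            for r in regions.table.itertuples(index=False):
                if min(te.end, r.end) - max(te.start, r.start) >= 1:
                    slow.add(te.te_id)
                    break
        assert fast == slow


class TestChromosomeView:
    def test_identical_samples_give_zero_log2(self):
        reads = placements(
            "s", [("chr1", int(p), "+") for p in range(0, 300_000, 30)]
        )
        view = chromosome_view(
            reads, reads, {"chr1": 300_000}, bin_bp=100_000, smooth_iters=0
        )
        assert np.allclose(view.values["chr1"], 0.0)

    def test_density_mode_units(self):
        reads = placements("s", [("chr1", p, "+") for p in range(100)])
        dens, _ = chromosome_view(
            reads,
            reads,
            {"chr1": 100_000},
            bin_bp=100_000,
            smooth_iters=0,
            mode="density",
        )
        # 100 reads / 100000 bp / (100/1e6) million reads
        assert dens.values["chr1"][0] == pytest.approx(
            100 / 100_000 / (100 / 1e6)
        )

    def test_smoothing_zero_equals_unsmoothed(self, tiny_genome):
        from rerepseq.simulate import simulate_dna_reads

        wt = simulate_dna_reads(tiny_genome, "wt", seed=5)
        mut = simulate_dna_reads(tiny_genome, "mutant", seed=5)
        v0 = chromosome_view(
            mut, wt, tiny_genome.chrom_sizes, bin_bp=50_000, smooth_iters=0
        )
        v10 = chromosome_view(
            mut, wt, tiny_genome.chrom_sizes, bin_bp=50_000, smooth_iters=10
        )
        chrom = next(iter(v0.values))
        assert not np.allclose(v0.values[chrom], v10.values[chrom])


class TestHetFraction:
    def test_exact_fraction(self):
        reads = placements(
            "s",
            [("chr1", p, "+") for p in range(50)]
            + [("chr1", 10_000 + p, "+") for p in range(150)],
        )
        het = RegionSet.from_tuples([("chr1", 0, 100)])
        assert het_fraction(reads, het) == pytest.approx(0.25)

    def test_full_coverage_gives_one(self):
        reads = placements("s", [("chr1", p, "+") for p in range(100)])
        het = RegionSet.from_tuples([("chr1", 0, 1_000_000)])
        assert het_fraction(reads, het) == 1.0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            het_fraction(placements("s", []), RegionSet.from_tuples([]))

    def test_uniform_reads_recover_het_span_fraction(self):
        rng = np.random.default_rng(8)
        pos = rng.integers(0, 100_000, size=20_000)
        reads = placements("s", [("chr1", int(p), "+") for p in pos])
        het = RegionSet.from_tuples([("chr1", 20_000, 50_000)])  # 30%
        assert het_fraction(reads, het) == pytest.approx(0.30, abs=0.02)


class TestCompareHetFractions:
    def _sample(self, n_in, n_out):
        rows = [("chr1", i % 100, "+") for i in range(n_in)]
        rows += [("chr1", 10_000 + i, "+") for i in range(n_out)]
        return placements("s", rows)

    def test_identical_samples_give_p_one(self):
        het = RegionSet.from_tuples([("chr1", 0, 100)])
        a = self._sample(50, 50)
        res = compare_het_fractions(a, a, het)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_chi2_oracle(self):
        from scipy.stats import chi2_contingency

        het = RegionSet.from_tuples([("chr1", 0, 100)])
        a = self._sample(900, 100)
        b = self._sample(500, 500)
        res = compare_het_fractions(a, b, het)
        expected = chi2_contingency(
            [[900, 100], [500, 500]], correction=True
        )[1]
        assert res.p_value == pytest.approx(expected)
        assert res.method == "chi2_yates"

    def test_small_cells_use_exact_test(self):
        from scipy.stats import fisher_exact

        het = RegionSet.from_tuples([("chr1", 0, 100)])
        a = self._sample(3, 20)
        b = self._sample(15, 8)
        res = compare_het_fractions(a, b, het)
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(
            fisher_exact([[3, 20], [15, 8]])[1]
        )

    def test_symmetric_under_label_swap(self):
        het = RegionSet.from_tuples([("chr1", 0, 100)])
        a = self._sample(80, 20)
        b = self._sample(40, 60)
        assert compare_het_fractions(a, b, het).p_value == pytest.approx(
            compare_het_fractions(b, a, het).p_value
        )


class TestTeDnaDensity:
    def test_units(self, simple_tes):
        # 10 reads in the 1-kb TE4, library of exactly 1e6 reads
        rows = [("chr2", 50 + i, "+") for i in range(10)]
        rows += [("chr1", 5_000 + i, "+") for i in range(1_000_000 - 10)]
        reads = placements("s", rows)
        dens = te_dna_density(reads, simple_tes, ["TE4"])
        assert dens["TE4"] == pytest.approx(10.0)

    def test_zero_reads(self, simple_tes):
        reads = placements("s", [("chr1", 5_000, "+")])
        assert te_dna_density(reads, simple_tes, ["TE4"])["TE4"] == 0.0

    def test_unknown_te_rejected(self, simple_tes):
        reads = placements("s", [("chr1", 0, "+")])
        with pytest.raises(ValueError):
            te_dna_density(reads, simple_tes, ["nope"])


class TestRanksum:
    @staticmethod
    def _enumerated_p(a, b):
        # brute force: every split of the pooled values into samples of
        # sizes |a| and |b|, U statistic counted directly
        pooled = sorted(a) + sorted(b)
        n_a = len(a)

        def u_stat(sample_a, sample_b):
            return sum(x > y for x in sample_a for y in sample_b)

        u_obs = u_stat(a, b)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n_a):
            sa = [pooled[i] for i in idx]
            sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
            us.append(u_stat(sa, sb))
        n = len(us)
        cnt_le = sum(u <= u_obs for u in us)
        cnt_ge = sum(u >= u_obs for u in us)
        return min(1.0, 2 * min(cnt_le, cnt_ge) / n)

    def test_matches_exact_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert self._enumerated_p(a, b) == pytest.approx(0.1)
        assert ranksum_compare(a, b) == pytest.approx(0.1)

    def test_enumeration_oracle_on_random_samples(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            a = rng.normal(size=4).tolist()
            b = rng.normal(size=5).tolist()
            assert ranksum_compare(a, b) == pytest.approx(
                self._enumerated_p(a, b)
            )

    def test_identical_multisets_give_p_one(self):
        assert ranksum_compare([1, 2, 3], [1, 2, 3]) == 1.0

    def test_symmetric_in_sample_order(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=8), rng.normal(size=5) + 1
        assert ranksum_compare(a, b) == pytest.approx(ranksum_compare(b, a))

    def test_all_tied_returns_one(self):
        assert ranksum_compare([2, 2], [2, 2, 2]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum_compare([], [1.0])
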