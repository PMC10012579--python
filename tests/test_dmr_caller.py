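"""Smoothing, per-CpG testing, grouping, origin classification, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import imprintatlas as ia
from imprintatlas.io_formats import Dmr
from conftest import jaccard


class TestSmoothing:
    def test_constant_input_is_fixed_point(self):
        pos = np.arange(0, 1000, 100)
        cov = np.full(10, 20)
        meth = (cov * 0.8).astype(int)
        out = ia.smooth_methylation(pos, meth, cov)
        assert out == pytest.approx(np.full(10, 0.8))

    def test_single_cpg_keeps_raw_fraction(self):
        out = ia.smooth_methylation(np.array([500]), np.array([3]),
                                    np.array([10]))
        assert out == pytest.approx([0.3])

    def test_step_profile_matches_weighted_mean_oracle(self):
        """0% -> 100% step: each smoothed value equals the hand-computed
        coverage-weighted mean over the +/-250 bp window."""
        pos = np.array([0, 100, 200, 300, 400, 500])
        cov = np.array([10, 20, 10, 40, 10, 20])
        meth = np.array([0, 0, 0, 40, 10, 20])   # step to 100% at pos 300
        out = ia.smooth_methylation(pos, meth, cov, span=500)
        for i, p in enumerate(pos):
            window = np.abs(pos - p) <= 250
            expected = meth[window].sum() / cov[window].sum()
            assert out[i] == pytest.approx(expected)

    def test_empty_input(self):
        assert len(ia.smooth_methylation(np.array([]), np.array([]),
                                         np.array([]))) == 0


class TestPerCpgTest:
    def test_extreme_difference(self):
        p, delta = ia.test_cpg_diff(20, 0, 0, 20)
        assert delta == 100.0
        assert p < 1e-9
        assert p == pytest.approx(stats.fisher_exact([[20, 0], [0, 20]]).pvalue)

    def test_identical_proportions(self):
        p, delta = ia.test_cpg_diff(10, 10, 10, 10)
        assert delta == 0.0
        assert p == 1.0

    def test_low_coverage_not_significant(self):
        p, delta = ia.test_cpg_diff(1, 0, 0, 1)
        assert delta == 100.0
        assert p > 0.001   # a 1-read 2x2 cannot reach p < 0.001

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            ia.test_cpg_diff(0, 0, 5, 5)


class TestCallDmrs:
    def _stats_frame(self, pos, candidate, chrom="chr1"):
        n = len(pos)
        return pd.DataFrame({
            "chrom": chrom, "pos": pos, "delta": np.where(candidate, 90.0, 1.0),
            "p": np.where(candidate, 1e-6, 1.0), "candidate": candidate})

    def test_single_planted_block(self):
        pos = np.arange(0, 5000, 100)
        cand = (pos >= 1000) & (pos < 3000)
        dmrs = ia.call_dmrs(self._stats_frame(pos, cand))
        assert len(dmrs) == 1
        assert dmrs[0].start == 1000
        assert dmrs[0].end == 2902   # last candidate 2900 + CpG dyad
        assert dmrs[0].n_cpg == 20

    def test_no_candidates_empty(self):
        pos = np.arange(0, 5000, 100)
        assert ia.call_dmrs(self._stats_frame(pos, np.zeros(len(pos), bool))) == []

    def test_blocks_separated_by_large_gap_split(self):
        pos = np.array([0, 100, 200, 1500, 1600, 1700])
        cand = np.ones(6, bool)
        dmrs = ia.call_dmrs(self._stats_frame(pos, cand), min_len=50)
        assert len(dmrs) == 2

    def test_row_order_invariance(self):
        pos = np.arange(0, 5000, 100)
        cand = (pos >= 1000) & (pos < 3000)
        frame = self._stats_frame(pos, cand)
        shuffled = frame.sample(frac=1, random_state=1)
        a = ia.call_dmrs(frame)
        b = ia.call_dmrs(shuffled)
        assert [(d.start, d.end) for d in a] == [(d.start, d.end) for d in b]

    def test_min_cpgs_and_min_len_gates(self):
        pos = np.array([0, 100, 200])
        dmrs = ia.call_dmrs(self._stats_frame(pos, np.ones(3, bool)),
                            min_cpgs=4)
        assert dmrs == []
        pos = np.array([0, 10, 20])
        dmrs = ia.call_dmrs(self._stats_frame(pos, np.ones(3, bool)),
                            min_len=50)
        assert dmrs == []


class TestMergeDmrSets:
    def test_overlapping_tissue_calls_union(self):
        a = [Dmr(chrom="chr1", start=100, end=300, n_cpg=5, tissues=("epiblast",))]
        b = [Dmr(chrom="chr1", start=250, end=500, n_cpg=4, tissues=("EPC",))]
        merged = ia.merge_dmr_sets(a, b)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 500)
        assert merged[0].tissues == ("EPC", "epiblast")

    def test_disjoint_intervals_kept(self):
        a = [Dmr(chrom="chr1", start=100, end=200)]
        b = [Dmr(chrom="chr1", start=300, end=400)]
        assert len(ia.merge_dmr_sets(a, b)) == 2


class TestSummaries:
    def _cpgs(self, rows):
        return pd.DataFrame(rows, columns=[
            "chrom", "pos", "sample_id", "allele", "meth_reads", "unmeth_reads"])

    def test_allelic_coverage_one_suffices(self):
        cpgs = self._cpgs([("chr1", p, "EPC", "maternal", 1, 0)
                           for p in (10, 20, 30)])
        d = ia.summarize_dmr_allelic_meth(Dmr(chrom="chr1", start=0, end=100), cpgs)
        assert d.means["EPC_maternal"] == pytest.approx(100.0)
        assert d.cpg_counts["EPC_maternal"] == 3

    def test_total_track_needs_five_reads(self):
        cpgs = self._cpgs([("chr1", 10, "EPC", "total", 2, 2),   # cov 4: dropped
                           ("chr1", 20, "EPC", "total", 5, 0)])
        d = ia.summarize_dmr_allelic_meth(Dmr(chrom="chr1", start=0, end=100), cpgs)
        assert d.cpg_counts["EPC_total"] == 1
        assert d.means["EPC_total"] == pytest.approx(100.0)

    def test_empty_overlap_gives_no_mean(self):
        cpgs = self._cpgs([("chr1", 500, "EPC", "maternal", 1, 0)])
        d = ia.summarize_dmr_allelic_meth(Dmr(chrom="chr1", start=0, end=100), cpgs)
        assert d.means == {} and d.cpg_counts == {}


class TestOriginClassification:
    def _dmr(self, **means):
        d = Dmr(chrom="chr1", start=0, end=100)
        d.means = means
        return d

    def test_gametic_maternal(self):
        d = self._dmr(oocyte=95, sperm=5, epiblast_maternal=90,
                      epiblast_paternal=10, EPC_maternal=88, EPC_paternal=9)
        assert ia.classify_dmr_origin(d) == "gametic_maternal"
        assert set(d.tissues) == {"epiblast", "EPC"}

    def test_somatic_maternal_epc_only(self):
        d = self._dmr(oocyte=5, sperm=5, epiblast_maternal=10,
                      epiblast_paternal=8, EPC_maternal=80, EPC_paternal=5)
        assert ia.classify_dmr_origin(d) == "somatic_maternal"
        assert d.tissues == ("EPC",)

    def test_gametes_hypermethylated(self):
        d = self._dmr(oocyte=90, sperm=88, EPC_maternal=80, EPC_paternal=10)
        assert ia.classify_dmr_origin(d) == "gametes_hypermethylated"

    def test_gametic_paternal_mirror(self):
        d = self._dmr(oocyte=5, sperm=95, epiblast_maternal=10,
                      epiblast_paternal=90)
        assert ia.classify_dmr_origin(d) == "gametic_paternal"

    def test_missing_gamete_summary_ambiguous(self):
        d = self._dmr(EPC_maternal=80, EPC_paternal=5)
        assert ia.classify_dmr_origin(d) == "ambiguous"


class TestFinalFilter:
    def _dmr(self, counts, means):
        d = Dmr(chrom="chr1", start=0, end=100)
        d.cpg_counts = counts
        d.means = means
        return d

    def test_low_cpg_sample_dropped(self):
        d = self._dmr({"oocyte": 5, "sperm": 1, "EPC_maternal": 5,
                       "EPC_paternal": 5},
                      {"EPC_maternal": 90.0, "EPC_paternal": 5.0})
        assert ia.final_filter([d], ("oocyte", "sperm", "EPC_maternal",
                                     "EPC_paternal")) == []

    def test_low_delta_dropped_high_delta_kept(self):
        required = ("oocyte", "sperm", "EPC_maternal", "EPC_paternal")
        counts = dict.fromkeys(required, 4)
        low = self._dmr(counts, {"EPC_maternal": 50.0, "EPC_paternal": 5.0})
        high = self._dmr(counts, {"EPC_maternal": 65.0, "EPC_paternal": 5.0})
        kept = ia.final_filter([low, high], required)
        assert kept == [high]


class TestEndToEnd:
    def test_planted_dmrs_recovered(self, meth_sim):
        """Every planted DMR is recovered (Jaccard >= 0.8) with its exact
        origin label; no extra DMRs are called."""
        cpgs, truth = meth_sim
        dmrs = ia.call_parent_of_origin_dmrs(cpgs)
        assert len(dmrs) == len(truth.dmrs)
        kind_of = {"gametic_maternal": "gametic_maternal",
                   "gametic_paternal": "gametic_paternal",
                   "somatic_maternal": "somatic_maternal"}
        for r in truth.dmrs.itertuples():
            match = [d for d in dmrs
                     if jaccard((d.start, d.end), (r.start, r.end)) >= 0.8]
            assert len(match) == 1
            assert match[0].origin == kind_of[r.kind]
            if r.kind.startswith("somatic"):
                assert match[0].tissues == ("EPC",)

    def test_identical_methylomes_give_no_dmrs(self):
        cfg = ia.SimConfig(seed=31, planted_dmrs=[], n_cpgs=4000)
        cpgs, _ = ia.simulate_methylomes(cfg)
        assert ia.call_parent_of_origin_dmrs(cpgs) == []
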