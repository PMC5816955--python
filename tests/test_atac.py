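import numpy as np
import pandas as pd
import pytest

from lbt2kit import atac, synthio
from lbt2kit.atac import PositionWeightMatrix
from lbt2kit.io import GeneModel
from lbt2kit.synthio import SimConfig


@pytest.fixture(scope="module")
def atac_sim():
    cfg = SimConfig(
        seed=7,
        n_peaks=100,
        mean_fragments_per_peak=1500.0,
        footprint_sites=tuple((i, 150, 12) for i in range(0, 100, 10)),
    )
    return cfg, synthio.simulate_atac(cfg)


class TestPeriodicity:
    def test_delta_ladder_gives_exact_period(self):
        lengths = np.repeat([200, 400, 600], [3000, 2000, 1000])
        assert atac.estimate_periodicity(lengths).period == 200

    def test_uniform_lengths_not_significant(self):
        lengths = np.random.default_rng(0).integers(50, 701, 50_000)
        res = atac.estimate_periodicity(lengths, seed=0)
        assert res.pvalue > 0.05

    def test_subnucleosomal_only_not_significant(self):
        cfg = SimConfig(subnucleosomal_fraction=1.0)
        lengths = synthio.sample_fragment_lengths(cfg, 100_000, np.random.default_rng(3))
        assert atac.estimate_periodicity(lengths, seed=3).pvalue > 0.05

    def test_default_mixture_recovers_200bp(self):
        cfg = SimConfig()
        periods = []
        for s in range(1, 6):
            lengths = synthio.sample_fragment_lengths(cfg, 100_000, np.random.default_rng(s))
            periods.append(atac.estimate_periodicity(lengths, seed=s).period)
        assert abs(np.median(periods) - 200) <= 10

    def test_invariant_to_order_and_subsampling(self):
        cfg = SimConfig()
        rng = np.random.default_rng(9)
        lengths = synthio.sample_fragment_lengths(cfg, 120_000, rng)
        base = atac.estimate_periodicity(lengths, seed=0).period
        assert atac.estimate_periodicity(lengths[::-1], seed=0).period == base
        for s in range(5):
            sub = np.random.default_rng(s).choice(lengths, 40_000, replace=False)
            assert abs(atac.estimate_periodicity(sub, seed=s).period - base) <= 10

    def test_too_few_fragments_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            atac.estimate_periodicity(np.array([200] * 999))


def _peak(chrom, start, end, score=10.0, summit=None):
    return pd.DataFrame(
        [[chrom, start, end, "p", score, ".", score, 1.0, 1.0,
          summit if summit is not None else (end - start) // 2]],
        columns=["chrom", "start", "end", "name", "score", "strand", "signal",
                 "pvalue", "qvalue", "summit"],
    )


class TestClassifyPeaks:
    genes = [
        GeneModel("g1", "chr1", "+", 1000, 5000, [(1000, 1500), (3000, 5000)]),
    ]

    def test_upstream_summit_is_promoter(self):
        classes, _ = atac.classify_peaks(_peak("chr1", 900, 1000, summit=50), self.genes)
        assert classes[0] == "promoter"  # summit 950, window [0, 1100)

    def test_intron_by_precedence(self):
        classes, _ = atac.classify_peaks(_peak("chr1", 1900, 2100), self.genes)
        assert classes[0] == "intron"  # inside span, outside exons

    def test_exon(self):
        classes, _ = atac.classify_peaks(_peak("chr1", 3200, 3400), self.genes)
        assert classes[0] == "exon"

    def test_minus_strand_promoter_window(self):
        minus = [GeneModel("g2", "chr1", "-", 1000, 5000, [(1000, 5000)])]
        # TSS = 4999; promoter covers [4999-100+1, 4999+1000+1) = [4900, 6000)
        classes, _ = atac.classify_peaks(_peak("chr1", 5400, 5600), minus)
        assert classes[0] == "promoter"

    def test_unknown_chromosome_is_intergenic(self, caplog):
        classes, _ = atac.classify_peaks(_peak("chrX", 100, 300), self.genes)
        assert classes[0] == "intergenic"
        assert "absent" in caplog.text

    def test_fractions_sum_to_one(self, atac_sim):
        _, (genes, _, peaks, _) = atac_sim
        _, fractions = atac.classify_peaks(peaks, genes)
        assert fractions.sum() == pytest.approx(1.0)

    def test_planted_fractions_recovered(self, atac_sim):
        cfg, (genes, _, peaks, truth) = atac_sim
        classes, fractions = atac.classify_peaks(peaks, genes)
        planted = pd.Series(truth.peak_class).value_counts(normalize=True)
        for cls in ("promoter", "intron"):
            assert abs(fractions[cls] - planted.get(cls, 0.0)) <= 0.05


class TestTopPeaks:
    def test_highest_scores_kept(self):
        peaks = pd.concat(
            [_peak("chr1", 0, 10, 5), _peak("chr1", 20, 30, 9), _peak("chr1", 40, 50, 1)]
        )
        out = atac.top_peaks(peaks, n=2)
        assert sorted(out["score"]) == [5, 9]

    def test_tie_break_lexicographic(self):
        peaks = pd.concat([_peak("chr2", 5, 10, 7), _peak("chr1", 50, 60, 7)])
        out = atac.top_peaks(peaks, n=1)
        assert out["chrom"].iloc[0] == "chr1"

    def test_zero_and_overflow(self, caplog):
        peaks = _peak("chr1", 0, 10, 5)
        assert len(atac.top_peaks(peaks, n=0)) == 0
        assert len(atac.top_peaks(peaks, n=10)) == 1


class TestTssProfile:
    def test_centered_fragments_peak_at_center(self):
        genes = [GeneModel("g", "chr1", "+", 10_000, 12_000, [(10_000, 12_000)])]
        frags = pd.DataFrame(
            {"chrom": "chr1", "start": [9_950] * 100, "end": [10_050] * 100}
        )
        prof = atac.tss_profile(frags, genes)
        assert abs(prof.loc[prof["density"].idxmax(), "position"]) <= 25.0

    def test_minus_strand_orientation(self):
        # fragment 100 bp 3' of a minus-strand TSS maps to +100 after orientation
        genes = [GeneModel("g", "chr1", "-", 5_000, 10_000, [(5_000, 10_000)])]
        tss = 9_999
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [tss - 100 - 25], "end": [tss - 100 + 25]})
        prof = atac.tss_profile(frags, genes)
        hit = prof.loc[prof["density"] > 0, "position"]
        assert len(hit) == 1 and 50 <= hit.iloc[0] <= 150

    def test_simulated_central_enrichment(self, atac_sim):
        _, (genes, frags, _, _) = atac_sim
        prof = atac.tss_profile(frags, genes)
        assert prof.attrs["central_enrichment"] > 2


class TestMaxPeakPerGene:
    genes = [
        GeneModel("g1", "chr1", "+", 1_000, 2_000, [(1_000, 2_000)]),
        GeneModel("g2", "chr1", "+", 50_000, 60_000, [(50_000, 60_000)]),
    ]

    def test_max_of_assigned_scores(self):
        peaks = pd.concat([_peak("chr1", 900, 1100, 50), _peak("chr1", 1400, 1600, 80)])
        table, assign = atac.max_peak_per_gene(peaks, self.genes)
        assert table.set_index("gene").loc["g1", "max_peak_score"] == 80
        assert (assign == 0).all()

    def test_gene_without_peak_scores_zero(self):
        peaks = _peak("chr1", 900, 1100, 50)
        table, _ = atac.max_peak_per_gene(peaks, self.genes)
        assert table.set_index("gene").loc["g2", "max_peak_score"] == 0

    def test_every_peak_assigned_once(self, atac_sim):
        _, (genes, _, peaks, _) = atac_sim
        _, assign = atac.max_peak_per_gene(peaks, genes)
        assert (assign >= 0).all() and len(assign) == len(peaks)

    def test_expressed_genes_more_accessible(self, atac_sim):
        """Accessibility-expression association on planted ground truth."""
        _, (genes, _, peaks, truth) = atac_sim
        table, _ = atac.max_peak_per_gene(peaks, genes)
        level = pd.Series(truth.expression_level, index=[g.gene_id for g in genes])
        rho, p = atac.accessibility_expression_association(table, level)
        assert rho > 0 and p < 0.01
        scores = table.set_index("gene")["max_peak_score"]
        expressed = level > 0
        assert scores[expressed.values].median() > scores[~expressed.values].median()


class TestPwmScan:
    def test_literal_word_found_at_planted_positions(self):
        pwm = PositionWeightMatrix.from_consensus("GATTACA")
        seq = "T" * 20 + "GATTACA" + "C" * 20 + "GATTACA" + "A" * 5
        hits = atac.pwm_scan(seq, pwm, threshold=pwm.max_score)
        assert list(hits.loc[hits["strand"] == "+", "position"]) == [20, 47]

    def test_palindrome_hits_both_strands(self):
        pwm = PositionWeightMatrix.from_consensus("ACGT")  # reverse complement of itself
        seq = "TTTACGTTTT"
        hits = atac.pwm_scan(seq, pwm, threshold=pwm.max_score)
        plus = set(hits.loc[hits["strand"] == "+", "position"])
        minus = set(hits.loc[hits["strand"] == "-", "position"])
        assert plus == minus == {3}

    def test_n_handling(self):
        pwm = PositionWeightMatrix.from_consensus("AAAA")
        assert len(atac.pwm_scan("AANAA", pwm, threshold=-10)) == 0
        assert len(atac.pwm_scan("AANAA", pwm, threshold=-10, n_neutral=True)) > 0

    def test_match_count_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        word = "ACGTACGT"
        pwm = PositionWeightMatrix.from_consensus(word)
        hits = atac.pwm_scan(seq, pwm, threshold=pwm.max_score)
        # brute force enumeration of exact occurrences on both strands
        rc = word.translate(atac.COMPLEMENT)[::-1]
        expect_plus = [i for i in range(len(seq) - 7) if seq[i : i + 8] == word]
        expect_minus = [i for i in range(len(seq) - 7) if seq[i : i + 8] == rc]
        assert list(hits.loc[hits["strand"] == "+", "position"]) == expect_plus
        assert list(hits.loc[hits["strand"] == "-", "position"]) == expect_minus


class TestDetectNotch:
    def test_uniform_coverage_no_calls(self):
        assert atac.detect_notch(np.full(200, 30.0)) == []

    def test_constructed_notch_dip_ratio(self):
        cov = np.full(200, 30.0)
        cov[100:112] = 5.0
        calls = atac.detect_notch(cov)
        assert len(calls) == 1
        call = calls[0]
        assert (call.notch_start, call.notch_end) == (100, 112)
        assert call.dip_depth_ratio == pytest.approx(1 - 5 / 30, abs=1e-9)

    def test_short_region_skipped(self, caplog):
        assert atac.detect_notch(np.full(30, 10.0)) == []

    def test_width_out_of_range_ignored(self):
        cov = np.full(300, 30.0)
        cov[100:160] = 2.0  # 60 bp: too wide for a footprint
        assert atac.detect_notch(cov) == []

    def test_pwm_gating(self):
        cov = np.full(200, 30.0)
        cov[100:112] = 3.0
        pwm = PositionWeightMatrix.from_consensus("GGGGCGGGGC")
        seq = "A" * 200
        assert atac.detect_notch(cov, pwm=pwm, sequence=seq) == []
        seq2 = seq[:101] + "GGGGCGGGGC" + seq[111:]
        calls = atac.detect_notch(cov, pwm=pwm, sequence=seq2)
        assert len(calls) == 1 and calls[0].motif_position == 101

    def test_planted_footprint_recall_and_false_calls(self, atac_sim):
        _, (genes, frags, peaks, truth) = atac_sim
        planted = set(truth.footprints["peak"])
        recall_hits, false_calls, clean = 0, 0, 0
        fp = truth.footprints.set_index("peak")
        for _, pk in peaks.iterrows():
            cov = atac.cut_site_coverage(frags, pk["chrom"], pk["start"], pk["end"])
            calls = atac.detect_notch(cov)
            if pk["name"] in planted:
                want = fp.loc[pk["name"]]
                recall_hits += any(
                    c.notch_start < want["notch_end"] and c.notch_end > want["notch_start"]
                    for c in calls
                )
            else:
                clean += 1
                false_calls += len(calls)
        assert recall_hits / len(planted) >= 0.9
        assert false_calls <= max(1, clean // 100)
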