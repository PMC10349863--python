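import numpy as np
import pandas as pd
import pytest

from sigdyn.alterations import (
    ConfigurationError,
    cin_score,
    classify_gene_cn,
    classify_gene_snv,
    gene_alteration_calls,
    pathway_matrix,
    proliferation_score,
)
from sigdyn.genome import GeneInterval
from sigdyn.io import CopyNumberSegment, SomaticVariant

GENE = GeneInterval("chr1", 1000, 2000, "+", "BRCA2")


def _seg(nmaj, nmin, start=0, end=5000):
    return CopyNumberSegment("s", "chr1", start, end, nmaj, nmin)


class TestGeneCnRules:
    def test_amplification_at_twice_ploidy(self):
        call = classify_gene_cn(GENE, [_seg(3, 1)], ploidy=2.0)
        assert call.amp and not call.dele and not call.loh

    def test_hemizygous_deletion_is_del_and_loh(self):
        call = classify_gene_cn(GENE, [_seg(1, 0)], ploidy=2.0)
        assert call.dele and call.loh and not call.amp

    def test_diploid_region_in_wgd_sample_is_deleted(self):
        call = classify_gene_cn(GENE, [_seg(1, 1)], ploidy=4.0)
        assert call.dele and not call.amp

    def test_loh_without_loss_of_total_copy(self):
        call = classify_gene_cn(GENE, [_seg(2, 0)], ploidy=2.0)
        assert call.loh and not call.dele and not call.amp

    def test_amp_and_del_never_cooccur(self):
        for nmaj in range(1, 9):
            for nmin in range(0, nmaj + 1):
                for ploidy in (1.8, 2.0, 3.5, 4.0):
                    call = classify_gene_cn(GENE, [_seg(nmaj, nmin)], ploidy)
                    assert not (call.amp and call.dele)

    def test_maximal_overlap_segment_is_used(self):
        segs = [_seg(1, 1, 0, 1200), _seg(5, 1, 1200, 5000)]
        call = classify_gene_cn(GENE, segs, ploidy=2.0)
        assert call.amp  # 800 bp overlap beats 200 bp

    def test_no_overlap_flagged(self):
        call = classify_gene_cn(GENE, [CopyNumberSegment("s", "chr2", 0, 10, 1, 1)], 2.0)
        assert call.flag == "no-CN" and not (call.amp or call.dele or call.loh)


class TestGeneSnvRules:
    def test_missense_counts(self):
        v = SomaticVariant("chr1", 1500, "A", "C", 10, 10, consequence="missense_variant")
        assert classify_gene_snv([v], GENE)

    def test_synonymous_does_not_count(self):
        v = SomaticVariant("chr1", 1500, "A", "C", 10, 10, consequence="synonymous_variant")
        assert not classify_gene_snv([v], GENE)

    def test_variant_outside_gene_ignored(self):
        v = SomaticVariant("chr1", 100, "A", "C", 10, 10, consequence="missense_variant")
        assert not classify_gene_snv([v], GENE)

    def test_missing_consequence_is_configuration_error(self):
        v = SomaticVariant("chr1", 1500, "A", "C", 10, 10)
        with pytest.raises(ConfigurationError):
            classify_gene_snv([v], GENE)
        assert classify_gene_snv([v], GENE, consequence_allowlist=None)


class TestPathwayMatrix:
    def _calls(self):
        genes = ["g1", "g2", "g3"]
        samples = [f"s{i}" for i in range(10)]
        calls = {
            cls: pd.DataFrame(False, index=samples, columns=genes)
            for cls in ("SNV_indel", "AMP", "DEL", "LOH")
        }
        calls["DEL"].loc["s0", "g1"] = True
        calls["DEL"].loc["s1", "g2"] = True
        calls["AMP"].loc["s2", "g3"] = True
        return calls

    def test_pathway_fraction_arithmetic(self):
        membership = pd.DataFrame({"gene": ["g1", "g2", "g3"],
                                   "pathway": ["BER", "BER", "NER"]})
        m = pathway_matrix(self._calls(), membership)
        frac = m.fractions()
        assert frac.loc["BER", "DEL"] == pytest.approx(0.2)  # 2 of 10
        assert frac.loc["NER", "AMP"] == pytest.approx(0.1)
        assert frac.index[0] == "BER"  # ordered by decreasing DEL fraction

    def test_empty_pathway_has_zero_fractions(self):
        membership = pd.DataFrame({"gene": ["gX"], "pathway": ["TLS"]})
        m = pathway_matrix(self._calls(), membership)
        assert m.fractions().loc["TLS"].sum() == 0.0

    def test_fractions_monotone_under_added_member(self):
        small = pd.DataFrame({"gene": ["g1"], "pathway": ["BER"]})
        big = pd.DataFrame({"gene": ["g1", "g2"], "pathway": ["BER", "BER"]})
        f_small = pathway_matrix(self._calls(), small).fractions()
        f_big = pathway_matrix(self._calls(), big).fractions()
        assert (f_big.loc["BER"] >= f_small.loc["BER"]).all()


class TestPlantedAlterationRecovery:
    def test_planted_events_recovered_exactly(self, genome):
        """CN and SNV events planted in DDR genes are all recalled by the
        deterministic rules, with no calls in untouched genes."""
        from sigdyn.simulate import TruthRecord, plant_pathway_cn_events, simulate_sample

        genes = genome.genes[:6]
        t = TruthRecord(
            "s", "primary", 0.8, 2.0,
            exposures={"clonal": {"SBS1": 1.0}},
            planted_pathway_hits=[
                (genes[0].name, "AMP"),
                (genes[1].name, "DEL"),
                (genes[2].name, "LOH"),
                (genes[3].name, "SNV_indel"),
            ],
        )
        plant_pathway_cn_events(t, genome)
        vs, segs = simulate_sample(genome, t, n_snvs=50, seed=3)
        calls = gene_alteration_calls(
            {"s": vs}, {"s": segs}, {"s": 2.0}, genes,
        )
        assert calls["AMP"].loc["s", genes[0].name]
        assert calls["DEL"].loc["s", genes[1].name]
        assert calls["LOH"].loc["s", genes[1].name]  # hemizygous del implies LOH
        assert calls["LOH"].loc["s", genes[2].name]
        assert not calls["DEL"].loc["s", genes[2].name]  # pure LOH keeps total
        assert calls["SNV_indel"].loc["s", genes[3].name]
        for cls in ("AMP", "DEL", "LOH", "SNV_indel"):
            assert not calls[cls].loc["s", genes[4].name]
            assert not calls[cls].loc["s", genes[5].name]


class TestCinScore:
    LENGTHS = {"chr1": 100_000_000}

    def _segs(self, spans):
        # spans: list of (start, end, total_cn) on chr1
        return [CopyNumberSegment("s", "chr1", s, e, t, 0) for s, e, t in spans]

    def test_normal_genome_scores_zero(self):
        segs = {"s": self._segs([(0, 100_000_000, 2)])}
        score = cin_score(segs, {"s": 2.0}, self.LENGTHS)
        assert score.raw["s"] == 0

    def test_five_percent_span_rule(self):
        segs6 = {"s": self._segs([(0, 6_000_000, 3), (6_000_000, 100_000_000, 2)])}
        assert cin_score(segs6, {"s": 2.0}, self.LENGTHS).raw["s"] == 1
        segs4 = {"s": self._segs([(0, 4_000_000, 3), (4_000_000, 100_000_000, 2)])}
        assert cin_score(segs4, {"s": 2.0}, self.LENGTHS).raw["s"] == 0

    def test_abnormality_is_relative_to_ploidy(self):
        segs = {"s": self._segs([(0, 100_000_000, 4)])}
        assert cin_score(segs, {"s": 4.0}, self.LENGTHS).raw["s"] == 0
        assert cin_score(segs, {"s": 2.0}, self.LENGTHS).raw["s"] == 1

    def test_cohort_z_is_standardized(self):
        segs = {
            "a": self._segs([(0, 100_000_000, 3)]),
            "b": self._segs([(0, 100_000_000, 2)]),
            "c": self._segs([(0, 50_000_000, 5), (50_000_000, 100_000_000, 1)]),
        }
        score = cin_score(segs, {k: 2.0 for k in segs}, self.LENGTHS)
        assert score.z.mean() == pytest.approx(0.0, abs=1e-12)
        assert score.z.std(ddof=0) == pytest.approx(1.0)

    def test_zero_variance_cohort_gets_zero_z(self):
        segs = {k: self._segs([(0, 100_000_000, 2)]) for k in "ab"}
        score = cin_score(segs, {k: 2.0 for k in segs}, self.LENGTHS)
        assert (score.z == 0).all()


class TestProliferationScore:
    def test_sample_at_cohort_mean_scores_one(self):
        # s0 sits exactly at the cohort mean of every marker (symmetric cohort)
        expr = pd.DataFrame(
            {"m1": [5.0, 4, 6, 3, 7], "m2": [2.0, 1, 3, 0, 4], "other": [9.0, 1, 2, 3, 4]},
            index=[f"s{i}" for i in range(5)],
        )
        score = proliferation_score(expr, ["m1", "m2"])
        assert score["s0"] == pytest.approx(1.0, abs=1e-9)

    def test_one_sd_above_mean_scores_zero(self):
        expr = pd.DataFrame({"m1": [0.0, 1, 2, 3], "m2": [0.0, 1, 2, 3]},
                            index=list("abcd"))
        z = (3 - expr["m1"].mean()) / expr["m1"].std(ddof=0)
        score = proliferation_score(expr, ["m1", "m2"])
        assert score["d"] == pytest.approx(1 - z)

    def test_arrested_group_anticorrelates_with_score(self):
        """Samples with elevated G0 markers score lower."""
        rng = np.random.default_rng(17)
        n = 40
        arrested = np.arange(n) < 20
        expr = pd.DataFrame(
            {f"m{j}": rng.normal(0, 1, n) + 2.0 * arrested for j in range(5)},
            index=[f"s{i}" for i in range(n)],
        )
        score = proliferation_score(expr, [f"m{j}" for j in range(5)])
        assert score[arrested].mean() < score[~arrested].mean() - 1.0

    def test_all_markers_missing_is_an_error(self):
        expr = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ConfigurationError):
            proliferation_score(expr, ["m1"])
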