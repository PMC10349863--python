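import numpy as np
import pytest

from sigdyn._channels import ID83_CHANNELS, SBS96_CHANNELS, revcomp
from sigdyn.catalogue import (
    build_catalogue,
    classify_indel,
    classify_snv,
    normalize_indel,
    tmb,
)
from sigdyn.genome import SyntheticGenome
from sigdyn.io import SomaticVariant, ValidationError
from sigdyn.simulate import TruthRecord, simulate_sample

from _oracles import indel_channel_oracle


def _genome(seq):
    return SyntheticGenome(sequences={"chrT": seq}, dyads={"chrT": np.array([5])})


class TestClassifySnv:
    def test_purine_reference_is_reverse_complemented(self):
        g = _genome("ACGTA")
        c = classify_snv(SomaticVariant("chrT", 2, "G", "A", 10, 10), g)
        assert c.channel == "A[C>T]G"
        assert c.pyrimidine_strand == "-"

    def test_pyrimidine_reference_kept_forward(self):
        g = _genome("ATCAG")
        c = classify_snv(SomaticVariant("chrT", 2, "C", "T", 10, 10), g)
        assert c.channel == "T[C>T]A"
        assert c.pyrimidine_strand == "+"

    def test_ref_mismatch_raises(self):
        g = _genome("ACGTA")
        with pytest.raises(ValidationError, match="ref"):
            classify_snv(SomaticVariant("chrT", 2, "A", "T", 10, 10), g)

    def test_contig_edge_is_dropped(self):
        g = _genome("ACGTA")
        assert classify_snv(SomaticVariant("chrT", 0, "A", "T", 10, 10), g) is None

    def test_strand_folding_is_involution_consistent(self):
        """Describing the same event from the other strand yields the
        identical channel."""
        rng = np.random.default_rng(11)
        bases = "ACGT"
        for _ in range(200):
            tri = "".join(rng.choice(list(bases), 3))
            ref = tri[1]
            alt = rng.choice([b for b in bases if b != ref])
            g_fwd = _genome("AA" + tri + "AA")
            c_fwd = classify_snv(SomaticVariant("chrT", 3, ref, str(alt), 5, 5), g_fwd)
            g_rev = _genome("TT" + revcomp(tri) + "TT")
            c_rev = classify_snv(
                SomaticVariant("chrT", 3, revcomp(ref), revcomp(str(alt)), 5, 5), g_rev
            )
            assert c_fwd.channel == c_rev.channel
            assert c_fwd.pentamer == c_rev.pentamer


class TestClassifyIndel:
    def test_insertion_extending_homopolymer(self):
        # insert T immediately 3' of the TTT run
        g = _genome("ACGTTTACG")
        v = SomaticVariant("chrT", 2, "G", "GT", 5, 5)
        assert classify_indel(v, g) == "1:Ins:T:3"

    def test_deletion_with_microhomology(self):
        # delete TAG; the following sequence starts TA -> homology 2
        # (preceding base C so the representation is already left-aligned)
        seq = "ACCGC" + "TAG" + "TACCCGGAT" + "ACCGG" * 3
        g = _genome(seq)
        v = SomaticVariant("chrT", 4, "CTAG", "C", 5, 5)
        assert classify_indel(v, g) == "3:Del:M:2"

    def test_repeat_unit_deletion(self):
        # one CA copy removed from CACACA -> 2 bp unit, 3 copies in reference
        seq = "GGT" + "CACACA" + "TGGCCAAGGT"
        g = _genome(seq)
        v = SomaticVariant("chrT", 2, "TCA", "T", 5, 5)
        assert classify_indel(v, g) == "2:Del:R:2"

    def test_left_alignment_of_shiftable_deletion(self):
        seq = "GGATTTTCGG"
        g = _genome(seq)
        # deleting any single T is equivalent; classify from the rightmost form
        v = SomaticVariant("chrT", 5, "TT", "T", 5, 5)
        start, deleted, inserted = normalize_indel(seq, v.pos, v.ref, v.alt)
        assert (start, deleted, inserted) == (3, "T", "")
        assert classify_indel(v, g) == "1:Del:T:3"

    def test_agrees_with_exhaustive_oracle_on_random_indels(self, genome):
        """500 random indels classified identically by brute-force scanning."""
        rng = np.random.default_rng(17)
        seq = genome.sequences["chr1"]
        checked = 0
        while checked < 500:
            pos = int(rng.integers(50, len(seq) - 50))
            length = int(rng.integers(1, 7))
            anchor = seq[pos - 1]
            if rng.random() < 0.5:
                ref, alt = seq[pos - 1 : pos + length], anchor
            else:
                ins = "".join(rng.choice(list("ACGT"), length))
                if rng.random() < 0.5:  # often duplicate adjacent sequence
                    ins = seq[pos : pos + length]
                ref, alt = anchor, anchor + ins
            v = SomaticVariant("chr1", pos - 1, ref, alt, 5, 5)
            mine = classify_indel(v, genome)
            if mine is None:
                continue
            assert mine == indel_channel_oracle(seq, pos - 1, ref, alt)
            checked += 1


class TestBuildCatalogue:
    def test_counts_are_conserved(self):
        g = _genome("ATCAG" * 20)
        vs = [SomaticVariant("chrT", 2 + 5 * i, "C", "T", 5, 5) for i in range(20)]
        cat, dropped = build_catalogue({"s": vs}, g, "sbs96")
        assert cat.loc["s", "T[C>T]A"] == 20
        assert cat.loc["s"].sum() == 20 and dropped["s"] == 0
        assert list(cat.columns) == list(SBS96_CHANNELS)

    def test_catalogues_are_additive_over_samples(self, genome, sbs_ref):
        t = TruthRecord("x", "primary", 0.9, 2.0, exposures={"clonal": {"SBS18": 1.0}})
        vs, _ = simulate_sample(genome, t, n_snvs=300, seed=4)
        a, b = vs[:150], vs[150:]
        cat_joint, _ = build_catalogue({"s": vs}, genome, "sbs96")
        cat_a, _ = build_catalogue({"s": a}, genome, "sbs96")
        cat_b, _ = build_catalogue({"s": b}, genome, "sbs96")
        assert (cat_a.loc["s"] + cat_b.loc["s"]).equals(cat_joint.loc["s"])

    def test_empty_sample_keeps_zero_row(self, genome):
        cat, _ = build_catalogue({"empty": []}, genome, "sbs96")
        assert cat.loc["empty"].sum() == 0

    def test_single_signature_sample_matches_profile(self, genome, sbs_ref):
        """Catalogue of a one-signature sample has cosine >= 0.99 to it."""
        t = TruthRecord("x", "primary", 0.9, 2.0, exposures={"clonal": {"SBS2": 1.0}})
        vs, _ = simulate_sample(genome, t, n_snvs=10_000, seed=5)
        cat, _ = build_catalogue({"x": vs}, genome, "sbs96")
        row = cat.loc["x"].to_numpy(float)
        col = sbs_ref.matrix["SBS2"].to_numpy()
        cos = row @ col / (np.linalg.norm(row) * np.linalg.norm(col))
        assert cos >= 0.99

    def test_id83_catalogue_channel_order(self, genome):
        t = TruthRecord("x", "primary", 0.9, 2.0, exposures={"clonal": {"SBS1": 1.0}})
        vs, _ = simulate_sample(genome, t, n_snvs=5, n_indels=40, seed=6)
        cat, dropped = build_catalogue({"x": vs}, genome, "id83")
        assert list(cat.columns) == list(ID83_CHANNELS)
        assert cat.loc["x"].sum() + dropped["x"] == 40


def test_tmb_counts_and_filter():
    vs = [
        SomaticVariant("chr1", 1, "A", "C", 10, 40),
        SomaticVariant("chr1", 2, "A", "C", 5, 40),
        SomaticVariant("chr1", 3, "A", "C", 2, 40),  # below support
        SomaticVariant("chr1", 4, "A", "AT", 9, 40),
        SomaticVariant("chr1", 5, "AG", "A", 8, 40),
    ]
    assert tmb(vs) == {"snvs": 2, "indels": 2, "total": 4}
    assert tmb(vs, min_alt_reads=0) == {"snvs": 3, "indels": 2, "total": 5}
    assert tmb([]) == {"snvs": 0, "indels": 0, "total": 0}
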