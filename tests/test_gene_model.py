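"""Gene-model validation and cDNA <-> genomic conversion."""

import numpy as np
import pytest

from g4snp.errors import (AlphabetError, CoordinateError, GeneStructureError,
                          OutOfRangeError, ReferenceMismatchError)
from g4snp.gene_model import (GeneModel, build_gene_model, cdna_to_genomic,
                              genomic_to_cdna, resolve_cdna_position,
                              verify_ref_base)
from g4snp.hgvs import parse_hgvs_cdna
from oracles import label_all_bases, random_model


class TestConstruction:
    def test_minimal_single_exon_model(self):
        m = build_gene_model("G", "A" * 50 + "ATG" + "A" * 147, [(0, 200)], 50)
        assert m.start_codon_offset == 50
        assert m.coding_length == 150

    def test_lowercase_sequence_is_uppercased(self):
        m = build_gene_model("G", "ttatggcaac", [(0, 10)], 2)
        assert m.sequence == "TTATGGCAAC"

    @pytest.mark.parametrize("exons, sco, exc", [
        ([(0, 10), (5, 20)], 2, GeneStructureError),     # overlap
        ([(20, 30), (0, 10)], 2, GeneStructureError),    # unsorted
        ([(0, 10), (20, 30)], 15, GeneStructureError),   # start codon in intron
        ([(0, 0)], 0, GeneStructureError),               # empty exon
        ([(0, 40)], 2, GeneStructureError),              # exon past sequence end
        ([], 0, GeneStructureError),                     # no exons
    ])
    def test_invariant_violations_rejected(self, exons, sco, exc):
        with pytest.raises(exc):
            build_gene_model("G", "A" * 30, exons, sco)

    def test_illegal_characters_rejected(self):
        with pytest.raises(AlphabetError, match="X"):
            build_gene_model("G", "ATGXATG", [(0, 7)], 0)


class TestCdnaToGenomic:
    """Spec'd toy-model positions, checked against the exhaustive labeller."""

    @pytest.mark.parametrize("text, offset", [
        ("c.1A>G", 2),        # definition: c.1 = A of ATG
        ("c.8C>A", 9),        # last coding base of exon 1
        ("c.9A>T", 20),       # first coding base of exon 2
        ("c.8+1T>A", 10),     # first intron base
        ("c.9-1T>A", 19),     # last intron base
        ("c.-1T>A", 1),       # transcribed 5'UTR
        ("c.-2T>A", 0),
        ("c.18C>A", 29),      # last coding base overall
    ])
    def test_toy_positions(self, toy_model, text, offset):
        loc = cdna_to_genomic(toy_model, parse_hgvs_cdna(text))
        assert loc.offset == offset
        assert loc.distance_from_start_codon == offset - 2

    def test_c1_has_distance_zero(self, toy_model):
        loc = cdna_to_genomic(toy_model, parse_hgvs_cdna("c.1A>G"))
        assert loc.distance_from_start_codon == 0

    def test_intron_anchored_minus_one_lands_just_before_its_exon(self):
        """c.K-1 must be the base immediately 5' of coding base K's exon,
        whichever intron that is (three-exon model, anchor in exon 3)."""
        seq = "T" * 5 + "ATGAA" + "T" * 6 + "CACAC" + "T" * 4 + "GAGAG" + "T" * 5
        m = GeneModel("G3", seq, [(5, 10), (16, 21), (25, 30)], 5)
        # coding bases: exon1 c.1-5, exon2 c.6-10, exon3 c.11-15
        loc = cdna_to_genomic(m, parse_hgvs_cdna("c.11-1G>A"))
        assert loc.offset == 24
        assert m.sequence[25] == m.sequence[loc.offset + 1]

    def test_utr5_continues_into_upstream_flank(self):
        seq = "A" * 20 + "T" * 2 + "ATG" + "C" * 15
        m = GeneModel("G", seq, [(20, 40)], 22)
        # -1, -2 transcribed; -3 and beyond continue into the flank
        assert cdna_to_genomic(m, parse_hgvs_cdna("c.-2A>T")).offset == 20
        assert cdna_to_genomic(m, parse_hgvs_cdna("c.-3A>T")).offset == 19
        assert cdna_to_genomic(m, parse_hgvs_cdna("c.-22A>T")).offset == 0

    def test_utr3_counts_into_downstream_flank(self):
        seq = "TT" + "ATG" + "C" * 15 + "AAAA"  # last exon ends at 20, 4 bp flank
        m = GeneModel("G", seq, [(0, 20)], 2)
        assert cdna_to_genomic(m, parse_hgvs_cdna("c.*1A>G")).offset == 20
        assert cdna_to_genomic(m, parse_hgvs_cdna("c.*4A>G")).offset == 23
        with pytest.raises(CoordinateError):
            cdna_to_genomic(m, parse_hgvs_cdna("c.*5A>G"))

    @pytest.mark.parametrize("text, exc", [
        ("c.19A>T", OutOfRangeError),    # beyond coding length (18)
        ("c.500A>T", OutOfRangeError),
        ("c.-100A>T", CoordinateError),  # past sequence start
        ("c.7+1A>T", GeneStructureError),   # anchor not exon-terminal
        ("c.10-1A>T", GeneStructureError),  # anchor not exon-first
        ("c.8+15A>T", CoordinateError),     # lands inside next exon
        ("c.9-15A>T", CoordinateError),     # lands inside previous exon
        ("c.18+1A>T", GeneStructureError),  # no intron after last exon
        ("c.1-1A>T", GeneStructureError),   # c.1 is not exon-first here
    ])
    def test_inconsistent_positions_rejected(self, toy_model, text, exc):
        with pytest.raises(exc):
            cdna_to_genomic(toy_model, parse_hgvs_cdna(text))


class TestGenomicToCdna:
    def test_start_codon_maps_to_c1(self, toy_model):
        pos = genomic_to_cdna(toy_model, 2)
        assert (pos.region, pos.anchor, pos.intron_offset) == ("coding", 1, 0)

    def test_last_intron_base_anchors_to_next_exon(self, toy_model):
        pos = genomic_to_cdna(toy_model, 19)
        assert (pos.region, pos.anchor, pos.intron_offset) == ("intronic", 9, -1)

    def test_intron_midpoint_tie_goes_upstream(self, toy_model):
        # intron [10, 20): offset 14 has d_prev = 5, d_next = 6 -> +5
        # offset 15 would tie at... d_prev = 6, d_next = 5 -> -5
        assert genomic_to_cdna(toy_model, 14).intron_offset == 5
        assert genomic_to_cdna(toy_model, 15).intron_offset == -5

    def test_base_upstream_of_atg_is_utr5_minus_one(self, toy_model):
        pos = genomic_to_cdna(toy_model, 1)
        assert (pos.region, pos.anchor) == ("utr5", -1)

    def test_out_of_bounds_offset_rejected(self, toy_model):
        with pytest.raises(CoordinateError):
            genomic_to_cdna(toy_model, 30)


class TestProperties:
    """Round-trip, monotonicity and oracle equivalence on random models."""

    def test_round_trip_identity_on_random_models(self, rng):
        """genomic_to_cdna o cdna_to_genomic is the identity on the
        positional fields for >= 1000 random legal descriptors."""
        checked = 0
        while checked < 1000:
            m = random_model(rng)
            for off, lab in enumerate(label_all_bases(m)):
                loc = resolve_cdna_position(m, lab.region, lab.anchor,
                                            lab.intron_offset)
                assert loc.offset == off
                back = genomic_to_cdna(m, loc.offset)
                assert (back.region, back.anchor, back.intron_offset) == \
                       (lab.region, lab.anchor, lab.intron_offset)
                checked += 1

    def test_agrees_with_exhaustive_labelling_oracle(self, rng):
        """Exon-walking conversion matches the naive per-base oracle on
        every base of 50 random models."""
        for _ in range(50):
            m = random_model(rng)
            for off, lab in enumerate(label_all_bases(m)):
                got = resolve_cdna_position(m, lab.region, lab.anchor,
                                            lab.intron_offset)
                assert got.offset == off, (m, off, lab)
                assert got.distance_from_start_codon == \
                       off - m.start_codon_offset

    def test_monotone_in_coding_anchor(self, rng):
        for _ in range(10):
            m = random_model(rng)
            offsets = [resolve_cdna_position(m, "coding", k).offset
                       for k in range(1, m.coding_length + 1)]
            assert offsets == sorted(offsets)
            assert len(set(offsets)) == len(offsets)


class TestVerifyRefBase:
    def test_match_mismatch_and_indeterminate(self):
        m = GeneModel("G", "ATGC", [(0, 4)], 0)
        v = parse_hgvs_cdna("c.3G>A")
        loc = cdna_to_genomic(m, v)
        assert verify_ref_base(m, loc, v).status == "match"

        v2 = parse_hgvs_cdna("c.3A>T")
        assert verify_ref_base(m, loc, v2).status == "mismatch"

        mn = GeneModel("G", "ATNC", [(0, 4)], 0)
        assert verify_ref_base(mn, loc, v).status == "indeterminate"

    def test_strict_mode_raises_with_strand_hint(self):
        m = GeneModel("G", "ATGC", [(0, 4)], 0)
        v = parse_hgvs_cdna("c.3A>T")
        loc = cdna_to_genomic(m, v)
        with pytest.raises(ReferenceMismatchError, match="strand"):
            verify_ref_base(m, loc, v, strict=True)
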