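"""Synthetic-data generator: determinism, validity, planted ground truth."""

import pytest

from g4snp.errors import ConfigurationError, PlantingError
from g4snp.fixtures import (TELOMERIC_MOTIF, label_bases, plant_g4,
                            plant_variants, simulate_dataset, simulate_gene,
                            write_dataset)
from g4snp.g4scan import find_g4_regions
from g4snp.gene_model import cdna_to_genomic, resolve_cdna_position
from g4snp.hgvs import parse_hgvs_cdna
from oracles import label_all_bases


class TestSimulateGene:
    def test_deterministic_under_seed(self):
        a = simulate_gene(seed=7)
        b = simulate_gene(seed=7)
        assert a.sequence == b.sequence
        assert a.exons == b.exons and a.start_codon_offset == b.start_codon_offset
        assert simulate_gene(seed=8).sequence != a.sequence

    def test_atg_literally_present_at_start_codon(self):
        m = simulate_gene(seed=3)
        assert m.sequence[m.start_codon_offset:m.start_codon_offset + 3] == "ATG"

    def test_models_pass_validation_over_many_seeds(self):
        # GeneModel's constructor is the validation oracle
        for seed in range(100):
            m = simulate_gene(n_exons=1 + seed % 5, seed=seed)
            assert m.exons[0][0] > 0

    def test_single_exon_gene_has_no_intronic_positions(self):
        m = simulate_gene(n_exons=1, seed=0)
        with pytest.raises(ConfigurationError, match="intronic"):
            plant_variants(m, 4, region_mix={"intronic": 1.0}, seed=0)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_gene(utr5_len=500, exon_len_range=(100, 120), seed=0)


class TestLabelBases:
    def test_agrees_with_independent_enumeration(self):
        for seed in (0, 1, 2):
            m = simulate_gene(n_exons=3, flank_len=50, seed=seed)
            ours = label_bases(m)
            ref = label_all_bases(m)
            assert [(l.region, l.anchor, l.intron_offset) for l in ours] == \
                   [(l.region, l.anchor, l.intron_offset) for l in ref]


class TestPlantG4:
    def test_plant_then_scan_recovers_exactly_one_region(self):
        m = simulate_gene(seed=11)
        m2, g4 = plant_g4(m, 200, clear_flank=30)
        regions = [r for r in find_g4_regions(m2.gene_name, m2.sequence,
                                              window=21, threshold=1.0)
                   if r.start < 400]
        assert len(regions) == 1
        assert regions[0].start <= g4.start and regions[0].end >= g4.end
        assert regions[0].score > 0

    def test_minus_orientation_scores_negative(self):
        m = simulate_gene(seed=11)
        m2, g4 = plant_g4(m, 200, orientation="-", clear_flank=30)
        hits = [r for r in find_g4_regions(m2.gene_name, m2.sequence)
                if r.start <= g4.start and r.end >= g4.end]
        assert len(hits) == 1 and hits[0].score < 0

    def test_overlapping_plants_rejected(self):
        m = simulate_gene(seed=11)
        m2, g4 = plant_g4(m, 200)
        with pytest.raises(PlantingError):
            plant_g4(m2, 210, existing=[g4])

    def test_planting_over_the_start_codon_rejected(self):
        m = simulate_gene(seed=11)
        with pytest.raises(PlantingError, match="ATG"):
            plant_g4(m, m.start_codon_offset - 5)


class TestPlantVariants:
    def test_every_planted_variant_round_trips(self):
        """parse -> map recovers the truth offset for 100% of planted
        variants, across region mixes and seeds."""
        for seed in range(5):
            m = simulate_gene(n_exons=4, seed=seed)
            planted = plant_variants(m, 20, seed=seed)
            for v in planted:
                loc = cdna_to_genomic(m, parse_hgvs_cdna(v.hgvs))
                assert loc.offset == v.offset
                assert loc.distance_from_start_codon == \
                       v.distance_from_start_codon

    def test_ref_base_matches_sequence_by_construction(self):
        m = simulate_gene(seed=2)
        for v in plant_variants(m, 15, seed=2):
            assert m.sequence[v.offset] == parse_hgvs_cdna(v.hgvs).ref_base

    def test_requested_mix_spans_all_four_classes(self):
        m = simulate_gene(seed=5)
        planted = plant_variants(
            m, 31, region_mix={"coding": .25, "intronic": .25,
                               "utr5": .25, "upstream": .25}, seed=5)
        assert len(planted) == 31
        assert {v.region_class for v in planted} == \
               {"coding", "intronic", "utr5", "upstream"}


class TestDataset:
    def test_dataset_files_written_and_reloadable(self, tmp_path):
        truths = simulate_dataset(n_genes=2, n_variants=6, seed=4)
        paths = write_dataset(tmp_path, truths)
        assert paths["truth"].exists()
        for t in truths:
            assert (tmp_path / f"{t.model.gene_name}.fasta").exists()
            assert (tmp_path / f"{t.model.gene_name}.structure.tsv").exists()
        lines = paths["variants"].read_text().splitlines()
        assert len(lines) == 6

    def test_variants_avoid_planted_motifs(self):
        for t in simulate_dataset(n_genes=2, n_variants=10, seed=9):
            for v in t.variants:
                for g in t.planted_g4s:
                    assert not (g.start <= v.offset < g.end)
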