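import numpy as np
import pytest

from limnobin.io_core import SequenceRecord
from limnobin.qc import gc_content
from limnobin.synthetic import (CommunityDesign, GenomeSpec, ReadSet,
                                fragment_genome, mutate_genome,
                                simulate_genome, simulate_reads,
                                tnf_l1_distance)

from .conftest import random_seq


class TestSimulateGenome:
    def test_seed_determinism(self):
        spec = GenomeSpec("G", 100_000, 0.6, 7, "V")
        a, _ = simulate_genome(spec)
        b, _ = simulate_genome(spec)
        assert a.residues == b.residues

    def test_gc_hits_target_at_1mb(self):
        g, _ = simulate_genome(GenomeSpec("G", 1_000_000, 0.60, 7, "V"))
        assert 59.0 <= gc_content([g]) <= 61.0

    def test_16s_copies_recorded(self, ref_db):
        spec = GenomeSpec("G", 100_000, 0.5, 9, "T1", n_16s_copies=2)
        _, truth = simulate_genome(spec, ref_db)
        ivs = [iv for iv in truth.ssu_intervals if iv[0] == "G"]
        assert len(ivs) == 2
        assert all(t == "T1" for *_, t in ivs)

    def test_markers_planted_as_gene_calls(self):
        spec = GenomeSpec("G", 100_000, 0.5, 9, "V",
                          marker_ids_planted=("M1", "M2", "M3"))
        _, truth = simulate_genome(spec)
        assert {c.gene_id for c in truth.marker_calls} == {"G|M1", "G|M2", "G|M3"}

    def test_distinct_seeds_give_distinct_tnf(self):
        a, _ = simulate_genome(GenomeSpec("A", 100_000, 0.5, 1, "V"))
        b, _ = simulate_genome(GenomeSpec("B", 100_000, 0.5, 2, "V"))
        assert tnf_l1_distance(a, b) > 0.05


class TestMutateGenome:
    def test_mu_zero_identity(self, small_genome):
        m = mutate_genome(small_genome, 0.0, 3)
        assert m.residues == small_genome.residues

    def test_hamming_identity_matches_rate(self, rng):
        g = SequenceRecord("g", random_seq(rng, 200_000))
        m = mutate_genome(g, 0.02, 11)
        a = g.codes
        b = m.codes
        ident = 100.0 * np.mean(a == b)
        assert ident == pytest.approx(98.0, abs=0.1)

    def test_different_seeds_differ(self, small_genome):
        m1 = mutate_genome(small_genome, 0.05, 1)
        m2 = mutate_genome(small_genome, 0.05, 2)
        assert m1.residues != m2.residues

    def test_rate_bounds(self, small_genome):
        with pytest.raises(ValueError):
            mutate_genome(small_genome, 0.5, 1)


class TestFragmentGenome:
    def test_lengths_conserved_and_min_respected(self, small_genome):
        contigs, truth = fragment_genome(small_genome,
                                         {"min_bp": 10_000, "mean_bp": 20_000}, 5)
        assert sum(len(c) for c in contigs) == len(small_genome)
        assert all(len(c) >= 10_000 for c in contigs)
        assert set(truth.contig_to_genome.values()) == {small_genome.id}

    def test_determinism(self, small_genome):
        law = {"min_bp": 10_000, "mean_bp": 20_000}
        a, _ = fragment_genome(small_genome, law, 5)
        b, _ = fragment_genome(small_genome, law, 5)
        assert [c.residues for c in a] == [c.residues for c in b]

    def test_annotations_remap_to_contig_coordinates(self):
        spec = GenomeSpec("G", 120_000, 0.5, 9, "V")
        g, truth = simulate_genome(spec)
        contigs, truth = fragment_genome(g, {"min_bp": 10_000, "mean_bp": 20_000},
                                         3, truth)
        seq_of = {c.id: c.residues for c in contigs}
        assert truth.gene_calls
        for call in truth.gene_calls:
            assert call.contig_id in seq_of
            assert call.end <= len(seq_of[call.contig_id])


class TestSimulateReads:
    def test_read_count_arithmetic(self, small_genome):
        design = CommunityDesign(
            [GenomeSpec(small_genome.id, len(small_genome), 0.5, 21, "V")],
            coverage=[[1.0]], read_length_bp=100, seed=5,
        )
        reads, truth = simulate_reads(design, [small_genome])
        assert len(reads["S1"]) == round(1.0 * len(small_genome) / 100)

    def test_error_free_reads_are_exact_substrings(self, small_genome):
        design = CommunityDesign(
            [GenomeSpec(small_genome.id, len(small_genome), 0.5, 21, "V")],
            coverage=[[0.05]], read_length_bp=80, per_base_error=0.0, seed=5,
        )
        reads, _ = simulate_reads(design, [small_genome])
        from limnobin._codes import revcomp

        genome = small_genome.residues
        for rec in reads["S1"]:
            assert rec.residues in genome or revcomp(rec.residues) in genome

    def test_desk_scale_guard(self, small_genome):
        design = CommunityDesign(
            [GenomeSpec(small_genome.id, len(small_genome), 0.5, 21, "V")],
            coverage=[[20000.0]], read_length_bp=100, seed=5,
        )
        with pytest.raises(ValueError, match="desk-scale"):
            simulate_reads(design, [small_genome])

    def test_reproducible_from_design(self, small_genome):
        design = CommunityDesign(
            [GenomeSpec(small_genome.id, len(small_genome), 0.5, 21, "V")],
            coverage=[[0.2]], read_length_bp=100, per_base_error=0.01, seed=5,
        )
        a, _ = simulate_reads(design, [small_genome])
        b, _ = simulate_reads(design, [small_genome])
        assert np.array_equal(a["S1"].codes, b["S1"].codes)


def test_readset_from_ragged_records_pads_with_n():
    rs = ReadSet.from_records("s", [SequenceRecord("a", "ACGT"),
                                    SequenceRecord("b", "AC")])
    assert rs.total_bases == 6
    assert rs.record(1).residues == "AC"
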