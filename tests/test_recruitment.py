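import numpy as np
import pytest

from limnobin.recruitment import (abundance_matrix, passes_recruitment,
                                  recruit, rpkg, rpkg_to_coverage)
from limnobin.synthetic import (CommunityDesign, GenomeSpec, simulate_genome,
                                simulate_reads)


class TestFilters:
    def test_passing_hit(self):
        assert passes_recruitment(96.0, 60, 1e-6)

    def test_identity_boundary_strict(self):
        assert not passes_recruitment(95.0, 60, 1e-6)

    def test_length_boundary_inclusive(self):
        assert passes_recruitment(96.0, 50, 1e-6)
        assert not passes_recruitment(96.0, 49, 1e-6)

    def test_evalue_boundary_inclusive(self):
        assert passes_recruitment(96.0, 60, 1e-5)
        assert not passes_recruitment(96.0, 60, 1.1e-5)


class TestRPKG:
    def test_arithmetic(self):
        assert rpkg(10_000, 1000, 1.0) == pytest.approx(10.0)
        assert rpkg(10_000, 2000, 0.5) == pytest.approx(10.0)

    def test_linearity(self):
        assert rpkg(500, 100, 2.0) == pytest.approx(rpkg(500, 100, 1.0) / 2)
        assert rpkg(1000, 100, 1.0) == pytest.approx(2 * rpkg(500, 100, 1.0))

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            rpkg(1, 0, 1.0)
        with pytest.raises(ValueError):
            rpkg(1, 1.0, 0)

    def test_coverage_conversion(self):
        # 10 RPKG is 1x coverage for 100 bp reads in a 1 Gbp metagenome
        assert rpkg_to_coverage(10.0, 100, 1.0) == pytest.approx(1.0)
        assert rpkg_to_coverage(10.0, 150, 1.0) == pytest.approx(1.5)
        assert rpkg_to_coverage(0.0, 100, 1.0) == 0.0


@pytest.fixture(scope="module")
def genome():
    return simulate_genome(GenomeSpec("Grec", 200_000, 0.55, 41, "V"))[0]


@pytest.fixture(scope="module")
def noise():
    return simulate_genome(
        GenomeSpec("noise", 200_000, 0.5, 90, "noise",
                   composition_concentration=50.0))[0]


class TestRecruit:
    def test_own_reads_recruited_and_counted_once(self, genome):
        design = CommunityDesign(
            [GenomeSpec(genome.id, len(genome), 0.55, 41, "V")],
            coverage=[[1.0]], read_length_bp=100, seed=3)
        reads, _ = simulate_reads(design, [genome])
        n, hits = recruit(reads["S1"], [genome])
        assert n == len(reads["S1"])
        assert len({h.query_id for h in hits}) == n

    def test_foreign_reads_not_recruited(self, genome, noise):
        design = CommunityDesign(
            [GenomeSpec(noise.id, len(noise), 0.5, 90, "noise")],
            coverage=[[1.0]], read_length_bp=100, seed=4)
        reads, _ = simulate_reads(design, [noise])
        n, _ = recruit(reads["S1"], [genome])
        assert n / len(reads["S1"]) < 0.001

    def test_rpkg_proportional_to_coverage(self, genome, noise):
        # fixed 3 Mbp metagenome per sample, varying target depth
        covs = [0.5, 1.0, 2.0, 4.0]
        design = CommunityDesign(
            [GenomeSpec(genome.id, len(genome), 0.55, 41, "V")],
            coverage=[covs], read_length_bp=100, per_base_error=0.005, seed=5,
            metagenome_target_gbp=0.003, sample_ids=[f"S{c}" for c in covs])
        reads, _ = simulate_reads(design, [genome], background=noise)
        records, wide = abundance_matrix({genome.id: [genome]}, reads)
        values = [wide.loc[genome.id, f"S{c}"] for c in covs]
        slope_fit = np.polyfit(covs, values, 1)
        pred = np.polyval(slope_fit, covs)
        ss_res = np.sum((np.array(values) - pred) ** 2)
        ss_tot = np.sum((np.array(values) - np.mean(values)) ** 2)
        assert 1 - ss_res / ss_tot >= 0.99

    def test_rpkg_scales_inversely_with_metagenome_size(self, genome, noise):
        # same genome depth, one sample padded with noise to twice the size
        design = CommunityDesign(
            [GenomeSpec(genome.id, len(genome), 0.55, 41, "V")],
            coverage=[[1.0, 1.0]], read_length_bp=100, seed=6,
            metagenome_target_gbp=0.0, sample_ids=["plain", "padded"])
        reads, _ = simulate_reads(design, [genome])
        design_pad = CommunityDesign(
            [GenomeSpec(genome.id, len(genome), 0.55, 41, "V")],
            coverage=[[1.0]], read_length_bp=100, seed=6,
            metagenome_target_gbp=2 * len(genome) / 1e9, sample_ids=["padded"])
        reads_pad, _ = simulate_reads(design_pad, [genome], background=noise)
        n_plain, _ = recruit(reads["plain"], [genome])
        n_pad, _ = recruit(reads_pad["padded"], [genome])
        r_plain = rpkg(n_plain, len(genome) / 1e3, reads["plain"].total_bases / 1e9)
        r_pad = rpkg(n_pad, len(genome) / 1e3, reads_pad["padded"].total_bases / 1e9)
        # padding doubles the metagenome, halving RPKG for the same depth
        assert r_pad == pytest.approx(r_plain / 2, rel=0.02)
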