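import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from limnobin._codes import revcomp
from limnobin.align import AlignmentHit
from limnobin.binning import (ContigFeatures, N_CANONICAL, cluster_contigs,
                              compute_features, coverage_estimate, pca,
                              taxonomy_vote, tnf_profile)
from limnobin.io_core import PipelineThresholds, SequenceRecord
from limnobin.synthetic import GenomeSpec, fragment_genome, simulate_genome

from .conftest import random_seq
from .oracles import canonical_tetramer_classes, covariance_eigen_pca

dna = st.text(alphabet="ACGTN", min_size=10, max_size=200)


class TestTNF:
    def test_canonical_class_count_matches_enumeration(self):
        assert N_CANONICAL == canonical_tetramer_classes() == 136

    def test_homopolymer_single_class(self):
        with pytest.warns(UserWarning):
            p = tnf_profile(SequenceRecord("s", "AAAAA"))
        assert p.freqs.max() == 1.0
        assert p.freqs.sum() == pytest.approx(1.0)

    @given(dna)
    @settings(max_examples=40, deadline=None)
    def test_reverse_complement_invariance(self, seq):
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = tnf_profile(SequenceRecord("s", seq))
                b = tnf_profile(SequenceRecord("s", revcomp(seq)))
        except ValueError:
            return  # too short / all-N windows
        assert np.array_equal(a.freqs, b.freqs)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tnf_profile(SequenceRecord("s", "ACG"))


class TestTaxonomyVote:
    def test_passing_contig(self):
        frac, ok = taxonomy_vote(15_000, ["V"] * 7 + ["x"] * 3, "V")
        assert (frac, ok) == (0.7, True)

    def test_vote_boundary_is_strict(self):
        frac, ok = taxonomy_vote(15_000, ["V"] * 6 + ["x"] * 4, "V")
        assert (frac, ok) == (0.6, False)

    def test_length_gate(self):
        frac, ok = taxonomy_vote(8_000, ["V"] * 9 + ["x"], "V")
        assert (frac, ok) == (0.9, False)

    def test_length_boundary_is_strict(self):
        assert taxonomy_vote(10_000, ["V"] * 10, "V")[1] is False
        assert taxonomy_vote(10_001, ["V"] * 10, "V")[1] is True

    def test_unlabelled_genes_count_in_denominator(self):
        frac, _ = taxonomy_vote(15_000, ["V", "V", None, None], "V")
        assert frac == 0.5

    def test_no_genes_undefined(self):
        frac, ok = taxonomy_vote(15_000, [], "V")
        assert np.isnan(frac) and ok is False


class TestPCA:
    def _profiles(self, rng, n=20):
        X = rng.dirichlet(np.ones(N_CANONICAL), size=n)
        from limnobin.binning import TNFProfile

        return [TNFProfile(f"c{i}", X[i]) for i in range(n)], X

    def test_variance_fractions_sum_to_one_over_all_components(self, rng):
        profiles, _ = self._profiles(rng)
        res = pca(profiles, 19)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self, rng):
        profiles, _ = self._profiles(rng)
        res = pca(profiles, 5)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-9)

    def test_matches_covariance_eigen_oracle(self, rng):
        profiles, X = self._profiles(rng)
        res = pca(profiles, 4)
        scores_o, comps_o, _ = covariance_eigen_pca(X, 4)
        assert np.allclose(np.abs(res.scores), np.abs(scores_o), atol=1e-8)
        assert np.allclose(res.scores, scores_o, atol=1e-8)

    def test_degenerate_matrix_rejected(self):
        from limnobin.binning import TNFProfile

        row = np.full(N_CANONICAL, 1.0 / N_CANONICAL)
        profiles = [TNFProfile(f"c{i}", row.copy()) for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            pca(profiles, 2)


class TestCoverage:
    def _hit(self, aln_len):
        return AlignmentHit("r", "c", 100.0, aln_len, aln_len, 1e-9, 0,
                            aln_len, 0, aln_len, "+")

    def test_arithmetic(self):
        hits = [self._hit(100) for _ in range(10)]
        assert coverage_estimate(1000, hits) == pytest.approx(1.0)

    def test_no_hits_zero(self):
        assert coverage_estimate(1000, []) == 0.0


class TestClustering:
    def test_three_genome_recovery(self, community, community_coverage):
        feats = compute_features(community.contigs, community.truth.gene_calls,
                                 "Verrucomicrobia", community_coverage)
        bins = cluster_contigs(feats, seed=1)
        assign = {c: b.bin_id for b in bins for c in b.contig_ids}
        kept = [f for f in feats if f.passes_taxon_filter]
        truth = [community.truth.contig_to_genome[f.contig_id] for f in kept]
        pred = [assign[f.contig_id] for f in kept]
        assert adjusted_rand_score(truth, pred) >= 0.95

    def test_binning_is_partition_of_filtered_set(self, community, community_coverage):
        feats = compute_features(community.contigs, community.truth.gene_calls,
                                 "Verrucomicrobia", community_coverage)
        bins = cluster_contigs(feats, seed=1)
        binned = [c for b in bins for c in b.contig_ids]
        assert len(binned) == len(set(binned))
        assert set(binned) == {f.contig_id for f in feats if f.passes_taxon_filter}

    def test_determinism(self, community, community_coverage):
        feats = compute_features(community.contigs, community.truth.gene_calls,
                                 "Verrucomicrobia", community_coverage)
        a = cluster_contigs(feats, seed=7)
        b = cluster_contigs(feats, seed=7)
        assert [x.contig_ids for x in a] == [x.contig_ids for x in b]

    def test_single_genome_collapses_to_one_bin(self):
        g, truth = simulate_genome(GenomeSpec("G", 300_000, 0.5, 77, "V"))
        contigs, truth = fragment_genome(g, {"min_bp": 10_000, "mean_bp": 25_000},
                                         5, truth)
        cov = {"S1": {c.id: 3.0 for c in contigs}}
        feats = compute_features(contigs, truth.gene_calls, "V", cov)
        bins = cluster_contigs(feats, seed=3)
        assert len(bins) == 1

    def test_unfiltered_contigs_never_binned(self):
        rng = np.random.default_rng(5)
        feats = []
        for i in range(10):
            feats.append(ContigFeatures(
                f"c{i}", rng.normal(size=3), 50.0 + i, np.array([2.0]),
                0.9 if i < 8 else 0.2, i < 8))
        bins = cluster_contigs(feats, seed=0)
        binned = {c for b in bins for c in b.contig_ids}
        assert "c8" not in binned and "c9" not in binned
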