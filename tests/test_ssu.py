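import numpy as np
import pytest

from limnobin import ssu
from limnobin.io_core import SequenceRecord
from limnobin.synthetic import (mutate_genome, simulate_ssu_read_mixture)

from .conftest import random_seq


@pytest.fixture(scope="module")
def cdb(ref_db):
    return ssu.dereplicate_references(ref_db)


@pytest.fixture(scope="module")
def profile(ref_db):
    return ssu.SSUProfile.fit(ref_db.records)


class TestDereplication:
    def test_identical_sequences_one_centroid(self, rng):
        seq = random_seq(rng, 1200)
        records = [SequenceRecord(f"r{i}", seq) for i in range(5)]
        db = ssu.ReferenceDB(records, {r.id: "T" for r in records})
        cdb = ssu.dereplicate_references(db)
        assert len(cdb.centroids) == 1
        assert sorted(cdb.members[cdb.centroids[0].id]) == [f"r{i}" for i in range(5)]

    def test_distant_pair_stays_separate(self, rng):
        a = SequenceRecord("a", random_seq(rng, 1200))
        b = mutate_genome(a, 0.15, 3)   # ~85% identity, below the 90% join rule
        db = ssu.ReferenceDB([a, SequenceRecord("b", b.residues)],
                             {"a": "T", "b": "T"})
        assert len(ssu.dereplicate_references(db).centroids) == 2

    def test_close_pair_merges(self, rng):
        a = SequenceRecord("a", random_seq(rng, 1200))
        b = mutate_genome(a, 0.03, 3)   # ~97% identity
        db = ssu.ReferenceDB([a, SequenceRecord("b", b.residues)],
                             {"a": "T", "b": "T"})
        assert len(ssu.dereplicate_references(db).centroids) == 1

    def test_members_partition_input(self, ref_db, cdb):
        all_members = [m for v in cdb.members.values() for m in v]
        assert sorted(all_members) == sorted(r.id for r in ref_db.records)


class TestCandidates:
    def test_planted_16s_reads_are_candidates(self, ref_db, cdb, rng):
        reads, labels = simulate_ssu_read_mixture(
            ref_db, 200, 1.0, "T1", 0.5, seed=8)
        found = ssu.detect_candidates(reads, cdb)
        assert len(found) / len(reads) >= 0.95

    def test_random_reads_rarely_candidates(self, cdb, rng):
        reads = [SequenceRecord(f"bg{i}", random_seq(rng, 150)) for i in range(1000)]
        found = ssu.detect_candidates(reads, cdb)
        assert len(found) / 1000 <= 0.01

    def test_empty_read_set(self, cdb):
        assert ssu.detect_candidates([], cdb) == {}


class TestVerification:
    def test_profile_needs_enough_references(self, ref_db):
        with pytest.raises(ValueError, match="50"):
            ssu.SSUProfile.fit(ref_db.records[:10])

    def test_true_candidates_mostly_verified(self, ref_db, profile):
        reads, _ = simulate_ssu_read_mixture(ref_db, 200, 1.0, "T1", 0.5,
                                             per_base_error=0.02, seed=9)
        verified = ssu.verify_ssu(reads, profile, seed=1)
        assert len(verified) / len(reads) >= 0.95

    def test_shuffled_candidates_fail_calibration(self, ref_db, profile, rng):
        reads, _ = simulate_ssu_read_mixture(ref_db, 200, 1.0, "T1", 0.5, seed=9)
        shuffled = [
            SequenceRecord(r.id, _shuffle_str(r, np.random.default_rng(i)))
            for i, r in enumerate(reads)
        ]
        verified = ssu.verify_ssu(shuffled, profile, seed=1)
        assert len(verified) / len(shuffled) <= 0.02

    def test_deterministic_given_seed(self, ref_db, profile):
        reads, _ = simulate_ssu_read_mixture(ref_db, 100, 1.0, "T1", 0.5, seed=9)
        a = ssu.verify_ssu(reads, profile, seed=4)
        b = ssu.verify_ssu(reads, profile, seed=4)
        assert [r.id for r in a] == [r.id for r in b]


def _shuffle_str(record, rng):
    from limnobin._codes import decode

    return decode(ssu.dinucleotide_shuffle(record.codes, rng))


def test_dinucleotide_shuffle_preserves_dinucleotide_counts(rng):
    from collections import Counter

    codes = np.frombuffer(bytes(rng.integers(0, 4, 300, dtype=np.uint8)), dtype=np.uint8)
    out = ssu.dinucleotide_shuffle(codes, rng)
    def dinucs(c):
        return Counter(zip(c[:-1].tolist(), c[1:].tolist()))
    assert dinucs(codes) == dinucs(out)
    assert out[0] == codes[0] and out[-1] == codes[-1]


class TestClassification:
    def test_threshold_boundaries(self):
        assert ssu.passes_classification(85.0, 120)
        assert ssu.passes_classification(80.0, 90)     # both inclusive
        assert not ssu.passes_classification(79.99, 120)
        assert not ssu.passes_classification(85.0, 89)

    def test_classified_taxon_matches_source(self, ref_db):
        reads, labels = simulate_ssu_read_mixture(ref_db, 300, 1.0, "T1", 0.5, seed=6)
        out = ssu.classify_reads(reads, ref_db)
        by_id = {c.read_id: c for c in out}
        correct = wrong = 0
        for rec, label in zip(reads, labels):
            c = by_id[rec.id]
            if c.status == "classified":
                correct += c.taxon == label
                wrong += c.taxon != label
        assert correct > 0.9 * len(reads)
        assert wrong <= 0.01 * len(reads)

    def test_taxon_iff_classified(self):
        with pytest.raises(ValueError):
            ssu.ClassifiedRead("r", "discarded", taxon="T")
        with pytest.raises(ValueError):
            ssu.ClassifiedRead("r", "classified", taxon=None)


class TestCascade:
    def test_statuses_partition_reads(self, ref_db, cdb, profile):
        reads, _ = simulate_ssu_read_mixture(ref_db, 500, 0.3, "T1", 0.2, seed=12)
        out = ssu.screen_reads(reads, ref_db, seed=2, cdb=cdb, profile=profile)
        assert len(out) == len(reads)
        assert {c.read_id for c in out} == {r.id for r in reads}
        assert {c.status for c in out} <= {
            "not_candidate", "candidate_rejected", "classified", "discarded"}

    def test_raising_identity_threshold_shrinks_classified_set(self, ref_db):
        reads, _ = simulate_ssu_read_mixture(ref_db, 200, 1.0, "T1", 0.5, seed=13)
        loose = {c.read_id for c in ssu.classify_reads(reads, ref_db, id_min=0.80)
                 if c.status == "classified"}
        tight = {c.read_id for c in ssu.classify_reads(reads, ref_db, id_min=0.95)
                 if c.status == "classified"}
        assert tight <= loose


class TestAbundance:
    def _cr(self, i, taxon):
        return ssu.ClassifiedRead(f"r{i}", "classified", taxon, 90.0, 100)

    def test_share_arithmetic(self):
        rows = [self._cr(i, "Verrucomicrobia") for i in range(30)]
        rows += [self._cr(100 + i, "Other") for i in range(120)]
        ab = ssu.taxon_relative_abundance(rows)
        assert ab["Verrucomicrobia"] == pytest.approx(20.0)
        assert sum(ab.values()) == pytest.approx(100.0)

    def test_single_taxon_is_100(self):
        ab = ssu.taxon_relative_abundance([self._cr(0, "X")])
        assert ab == {"X": 100.0}

    def test_no_classified_reads_is_an_error(self):
        with pytest.raises(ValueError, match="no classified"):
            ssu.taxon_relative_abundance(
                [ssu.ClassifiedRead("r", "discarded")])
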