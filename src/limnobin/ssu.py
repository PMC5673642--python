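"""Unassembled-read 16S rRNA screening cascade.

Four stages mirror the screening design for raw metagenome reads:

1. the reference set is dereplicated at 90 percent identity (greedy
   longest-first centroid clustering) to make candidate detection cheap;
2. a read is a *candidate* 16S fragment iff its best hit against the
   dereplicated set has e-value < 1e-5 (strict);
3. candidates are *verified* against a position-weight profile built from
   the reference alignment, with the score threshold calibrated so at most
   1 percent of dinucleotide-shuffled candidates would pass;
4. verified reads are classified against the FULL (non-dereplicated)
   reference set into the best hit's taxon iff identity >= 80 percent and
   alignment length >= 90 bp, otherwise discarded.

Per-taxon relative abundance is the share of classified reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._codes import revcomp_codes
from .align import ScoringScheme, SubjectIndex, best_hit_per_query, search
from .io_core import PipelineThresholds, SequenceRecord

SSU_SEED_BP = 12


@dataclass
class ReferenceDB:
    """Labelled 16S/18S reference sequences."""

    records: list
    taxon_of: dict

    def __post_init__(self) -> None:
        for r in self.records:
            if r.id not in self.taxon_of:
                raise ValueError(f"reference {r.id} has no taxon label")
        odd = [r.id for r in self.records if not 800 <= len(r) <= 2000]
        if odd:
            warnings.warn(
                f"{len(odd)} reference sequences outside the typical 800-2000 bp range"
            )


@dataclass
class ClusteredDB:
    """Centroid subset of a ReferenceDB plus the centroid->members map."""

    centroids: list
    members: dict          # centroid_id -> list of member record ids (incl. itself)
    taxon_of: dict


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    status: str            # not_candidate | candidate_rejected | classified | discarded
    taxon: str | None = None
    identity: float | None = None
    aln_len: int | None = None

    def __post_init__(self) -> None:
        if (self.taxon is not None) != (self.status == "classified"):
            raise ValueError("taxon must be present iff status is 'classified'")


def dereplicate_references(db: ReferenceDB, identity: float = 0.90,
                           scheme: ScoringScheme | None = None) -> ClusteredDB:
    """Greedy longest-first centroid clustering of the reference set.

    A record joins the first existing centroid it matches at >= ``identity``
    over >= 80 percent of its own length; otherwise it seeds a new centroid.
    """
    if not db.records:
        raise ValueError("empty reference db")
    scheme = scheme or ScoringScheme()
    order = sorted(db.records, key=lambda r: (-len(r), r.id))
    centroids: list[SequenceRecord] = []
    members: dict[str, list] = {}
    index: SubjectIndex | None = None
    for rec in order:
        joined = None
        if centroids:
            hits = search(rec, index, scheme)
            for h in hits:
                if h.identity >= identity * 100.0 and h.aln_len >= 0.8 * len(rec):
                    joined = h.subject_id
                    break
        if joined is None:
            centroids.append(rec)
            members[rec.id] = [rec.id]
            index = SubjectIndex(centroids, k=SSU_SEED_BP)
        else:
            members[joined].append(rec.id)
    return ClusteredDB(centroids, members, dict(db.taxon_of))


def detect_candidates(reads, cdb: ClusteredDB, evalue_max: float = 1e-5,
                      scheme: ScoringScheme | None = None) -> dict:
    """Candidate 16S fragments: best-hit e-value < evalue_max (strict).

    ``reads`` is any iterable of SequenceRecords (e.g. a synthetic ReadSet).
    Returns {read_id: best AlignmentHit} for candidates only.
    """
    scheme = scheme or ScoringScheme()
    index = SubjectIndex(cdb.centroids, k=SSU_SEED_BP)
    out = {}
    for rec in reads:
        hits = search(rec, index, scheme)
        if not hits:
            continue
        best = hits[0]
        if best.evalue < evalue_max:
            out[rec.id] = best
    return out


# ---------------------------------------------------------------------------
# position-weight profile verification


def dinucleotide_shuffle(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Altschul-Erikson shuffle preserving exact dinucleotide counts."""
    n = codes.size
    if n < 3:
        return codes.copy()
    seq = codes.astype(int).tolist()
    first, last = seq[0], seq[-1]
    edges = {v: [] for v in range(5)}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    vertices = [v for v in edges if edges[v]]
    for _ in range(10000):
        for v in vertices:
            lst = edges[v]
            perm = rng.permutation(len(lst))
            edges[v] = [lst[i] for i in perm]
        # last-edge graph must let every used vertex reach `last`
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last and u not in seen:
                seen.add(u)
                if not edges[u]:
                    break
                u = edges[u][-1]
            if u != last:
                ok = False
                break
        if ok:
            break
    counters = {v: 0 for v in edges}
    out = [first]
    u = first
    for _ in range(n - 1):
        nxt = edges[u][counters[u]]
        counters[u] += 1
        out.append(nxt)
        u = nxt
    return np.array(out, dtype=np.uint8)


class SSUProfile:
    """Log-odds position-weight model of the 16S gene built from references.

    References are placed onto the longest reference's coordinate system by
    their best un-gapped alignment offset; per-column base counts (with a
    0.5 pseudocount) against the pooled background give the log-odds matrix.
    A read is scored by its best un-gapped placement on either strand.
    """

    MIN_REFERENCES = 50

    def __init__(self, logodds: np.ndarray):
        self.logodds = logodds   # L x 4

    @classmethod
    def fit(cls, references: Sequence[SequenceRecord],
            scheme: ScoringScheme | None = None) -> "SSUProfile":
        if len(references) < cls.MIN_REFERENCES:
            raise ValueError(
                f"need >= {cls.MIN_REFERENCES} references to train, got {len(references)}"
            )
        scheme = scheme or ScoringScheme()
        template = max(references, key=len)
        L = len(template)
        counts = np.zeros((L, 4))
        tmpl_index = SubjectIndex([template], k=SSU_SEED_BP)
        for ref in references:
            codes = ref.codes
            if len(ref) == L:
                offset, oriented = 0, codes
            else:
                hits = search(ref, tmpl_index, scheme)
                if not hits:
                    continue
                h = hits[0]
                oriented = codes if h.s_strand == "+" else revcomp_codes(codes)
                q0 = h.q_start if h.s_strand == "+" else len(ref) - h.q_end
                offset = h.s_start - q0
            for i, c in enumerate(oriented):
                p = offset + i
                if 0 <= p < L and c < 4:
                    counts[p, c] += 1
        bg = counts.sum(axis=0)
        bg = (bg + 1.0) / (bg.sum() + 4.0)
        freqs = (counts + 0.5) / (counts.sum(axis=1, keepdims=True) + 2.0)
        return cls(np.log(freqs / bg[None, :]))

    def score(self, codes: np.ndarray) -> float:
        """Best un-gapped placement score over all offsets and both strands."""
        best = -np.inf
        for c in (codes, revcomp_codes(codes)):
            valid = c < 4
            cc = np.where(valid, c, 0)
            A = self.logodds[:, cc]           # L x r
            A[:, ~valid] = 0.0
            L, r = A.shape
            if L < r:
                continue
            n_off = L - r + 1
            s = np.zeros(n_off)
            for k in range(r):
                s += A[k : k + n_off, k]
            m = float(s.max())
            best = max(best, m)
        return best


def verify_ssu(candidates: Sequence[SequenceRecord], profile: SSUProfile,
               shuffle_fpr: float = 0.01, seed: int = 0) -> list[SequenceRecord]:
    """Keep candidates whose profile score beats the shuffle-calibrated threshold.

    The threshold is the (1 - shuffle_fpr) quantile of the scores of
    dinucleotide-shuffled copies of the candidates themselves, so by
    construction at most ~1 percent of shuffled candidates pass.
    """
    candidates = list(candidates)
    if not candidates:
        return []
    rng = np.random.default_rng(seed)
    shuffled_scores = np.array(
        [profile.score(dinucleotide_shuffle(c.codes, rng)) for c in candidates]
    )
    threshold = float(np.quantile(shuffled_scores, 1.0 - shuffle_fpr))
    return [c for c in candidates if profile.score(c.codes) > threshold]


def classify_reads(verified: Sequence[SequenceRecord], full_db: ReferenceDB,
                   id_min: float = 0.80, len_min: int = 90,
                   scheme: ScoringScheme | None = None) -> list[ClassifiedRead]:
    """Classify verified reads against the full reference set.

    A read takes its best hit's taxon iff identity >= id_min (inclusive) and
    alignment length >= len_min bp (inclusive); otherwise it is discarded.
    """
    scheme = scheme or ScoringScheme()
    index = SubjectIndex(full_db.records, k=SSU_SEED_BP)
    out = []
    for rec in verified:
        hits = search(rec, index, scheme)
        best = hits[0] if hits else None
        if best is not None and passes_classification(best.identity, best.aln_len,
                                                      id_min, len_min):
            out.append(
                ClassifiedRead(rec.id, "classified", full_db.taxon_of[best.subject_id],
                               best.identity, best.aln_len)
            )
        else:
            out.append(
                ClassifiedRead(rec.id, "discarded", None,
                               best.identity if best else None,
                               best.aln_len if best else None)
            )
    return out


def passes_classification(identity_pct: float, aln_len: int,
                          id_min: float = 0.80, len_min: int = 90) -> bool:
    """The two-threshold classification rule (both inclusive)."""
    return identity_pct >= id_min * 100.0 and aln_len >= len_min


def screen_reads(reads, db: ReferenceDB,
                 thresholds: PipelineThresholds | None = None,
                 seed: int = 0, cdb: ClusteredDB | None = None,
                 profile: SSUProfile | None = None) -> list[ClassifiedRead]:
    """Full cascade; every input read gets exactly one status."""
    th = thresholds or PipelineThresholds()
    reads = list(reads)
    if cdb is None:
        cdb = dereplicate_references(db, th.derep_identity)
    if profile is None:
        profile = SSUProfile.fit(db.records)
    candidates = detect_candidates(reads, cdb, th.candidate_evalue)
    cand_records = [r for r in reads if r.id in candidates]
    verified = verify_ssu(cand_records, profile, seed=seed)
    verified_ids = {r.id for r in verified}
    classified = {
        c.read_id: c
        for c in classify_reads(verified, db, th.classify_identity, th.classify_alnlen_bp)
    }
    out = []
    for r in reads:
        if r.id in classified:
            out.append(classified[r.id])
        elif r.id in verified_ids:   # pragma: no cover - classify covers all verified
            raise AssertionError
        elif r.id in candidates:
            out.append(ClassifiedRead(r.id, "candidate_rejected"))
        else:
            out.append(ClassifiedRead(r.id, "not_candidate"))
    return out


def taxon_relative_abundance(classified: Iterable[ClassifiedRead]) -> dict:
    """Percent of classified reads per taxon; sums to 100."""
    counts: dict[str, int] = {}
    total = 0
    for c in classified:
        if c.status == "classified":
            counts[c.taxon] = counts.get(c.taxon, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no classified reads")
    return {t: 100.0 * n / total for t, n in sorted(counts.items())}
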