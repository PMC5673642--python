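"""Seed-and-extend local nucleotide alignment with identity and e-values.

This is the single search engine behind 16S screening, ANI and fragment
recruitment, so the pipeline needs no external search tool.  Hits carry
the (identity, alignment length, e-value) triple every downstream filter
operates on.  Significance follows Karlin–Altschul statistics:
``E = K * m * n * exp(-lambda * score)`` with m the query length and n the
total length of the subject collection (database-size correction).

The search strategy is classic: exact k-mer seeds on both strands, x-drop
un-gapped extension along the seed diagonal, and a banded gapped refinement
(band 16) when the un-gapped alignment fails to cover the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._codes import encode, kmer_codes, revcomp_codes
from .io_core import SequenceRecord

_XDROP = 20
_BAND = 16


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring: match/mismatch rewards and affine gap costs.

    A gap of length g costs ``gap_open + g * gap_extend``.  ``K`` is the
    Karlin–Altschul prefactor (fixed constant); ``lam`` is solved from the
    match/mismatch scheme and base frequencies when not supplied.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    K: float = 0.621
    lam: float | None = None

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.lam is None:
            object.__setattr__(self, "lam", solve_lambda(self))


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float      # percent
    aln_len: int         # alignment columns
    score: int
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    s_strand: str


def solve_lambda(scheme: ScoringScheme, base_freqs: Sequence[float] = (0.25,) * 4) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda*s(i,j)) = 1, by bisection.

    Requires a negative expected pair score, otherwise no positive root
    exists and the scheme carries no significance statistics.
    """
    p = np.asarray(base_freqs, dtype=float)
    if p.size != 4 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("base_freqs must be a 4-vector summing to 1")
    p_match = float((p * p).sum())
    p_mismatch = 1.0 - p_match
    exp_score = p_match * scheme.match + p_mismatch * scheme.mismatch
    if exp_score >= 0:
        raise ValueError("invalid scheme: expected pair score must be negative")

    def f(lam: float) -> float:
        return (
            p_match * np.exp(lam * scheme.match)
            + p_mismatch * np.exp(lam * scheme.mismatch)
            - 1.0
        )

    hi = 1.0
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("invalid scheme: no positive root")
    lo = 1e-9
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class SubjectIndex:
    """Sorted k-mer position index over a subject collection.

    Built once per subject set; lookups are vectorised binary searches so a
    query's seeds are located in one call.
    """

    def __init__(self, subjects: Iterable[SequenceRecord], k: int = 12,
                 max_positions_per_kmer: int = 64):
        self.subjects = list(subjects)
        if k < 8:
            raise ValueError("seed length must be >= 8")
        self.k = k
        self.codes = [s.codes for s in self.subjects]
        self.total_len = int(sum(len(s) for s in self.subjects))
        kms, sidx, pos = [], [], []
        for i, c in enumerate(self.codes):
            km = kmer_codes(c, k)
            valid = km >= 0
            kms.append(km[valid])
            pos.append(np.nonzero(valid)[0].astype(np.int64))
            sidx.append(np.full(int(valid.sum()), i, dtype=np.int64))
        if kms:
            km_all = np.concatenate(kms)
            order = np.argsort(km_all, kind="stable")
            self._kmers = km_all[order]
            self._sidx = np.concatenate(sidx)[order]
            self._pos = np.concatenate(pos)[order]
        else:
            self._kmers = np.empty(0, dtype=np.int64)
            self._sidx = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
        self._unique = np.unique(self._kmers)
        self._cap = max_positions_per_kmer
        self._screen_set: np.ndarray | None = None

    @property
    def screen_kmers(self) -> np.ndarray:
        """Sorted union of subject k-mers and their reverse complements.

        Lets bulk prescreens check only the forward strand of each read.
        """
        if self._screen_set is None:
            k = self.k
            fwd = self._unique
            rc = np.zeros_like(fwd)
            tmp = fwd.copy()
            for _ in range(k):
                rc = (rc << 2) | (3 - (tmp & 3))
                tmp >>= 2
            self._screen_set = np.unique(np.concatenate([fwd, rc]))
        return self._screen_set

    def lookup(self, query_kmers: np.ndarray):
        """Yield (q_pos, subj_idx, s_pos) seed triples for all query k-mers."""
        lo = np.searchsorted(self._kmers, query_kmers, "left")
        hi = np.searchsorted(self._kmers, query_kmers, "right")
        out = []
        for qpos in np.nonzero(hi > lo)[0]:
            if query_kmers[qpos] < 0:
                continue
            a, b = int(lo[qpos]), int(hi[qpos])
            if b - a > self._cap:
                b = a + self._cap
            out.append((int(qpos), self._sidx[a:b], self._pos[a:b]))
        return out

    def screen(self, kmer_matrix: np.ndarray) -> np.ndarray:
        """Row mask: does any forward-strand k-mer occur on either subject strand?

        Used by bulk recruitment as a vectorised candidate prescreen.
        """
        ref = self.screen_kmers
        if ref.size == 0:
            return np.zeros(kmer_matrix.shape[0], dtype=bool)
        flat = kmer_matrix.reshape(-1)
        idx = np.minimum(np.searchsorted(ref, flat), ref.size - 1)
        present = (ref[idx] == flat) & (flat >= 0)
        return present.reshape(kmer_matrix.shape).any(axis=1)


def _ungapped_extend(q: np.ndarray, s: np.ndarray, qpos: int, spos: int, k: int,
                     scheme: ScoringScheme):
    """X-drop extension of an exact seed along its diagonal.

    Returns (q0, q1, s0, s1, score, matches) of the trimmed max-scoring
    segment containing the seed.
    """
    m, mm = scheme.match, scheme.mismatch
    # right of the seed
    score = k * m
    best = score
    bq1, bs1 = qpos + k, spos + k
    i, j = qpos + k, spos + k
    while i < q.size and j < s.size:
        score += m if (q[i] == s[j] and q[i] < 4) else mm
        i += 1
        j += 1
        if score > best:
            best, bq1, bs1 = score, i, j
        elif best - score > _XDROP:
            break
    # left of the seed
    score = best
    best2 = score
    bq0, bs0 = qpos, spos
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += m if (q[i] == s[j] and q[i] < 4) else mm
        if score > best2:
            best2, bq0, bs0 = score, i, j
        elif best2 - score > _XDROP:
            break
        i -= 1
        j -= 1
    matches = int(np.count_nonzero((q[bq0:bq1] == s[bs0:bs1]) & (q[bq0:bq1] < 4)))
    return bq0, bq1, bs0, bs1, int(best2), matches


def _banded_sw(q: np.ndarray, s: np.ndarray, d0: int, scheme: ScoringScheme,
               band: int = _BAND):
    """Banded affine local alignment restricted to diagonals d0 +/- band.

    Returns (score, q0, q1, s0, s1, matches, aln_len) of the best local
    path, or None when nothing scores above zero.
    """
    Lq, Ls = q.size, s.size
    mt, mm = float(scheme.match), float(scheme.mismatch)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    W = 2 * band + 1
    NEG = -1e18
    H_prev = [0.0] * W
    E_prev = [NEG] * W
    F_prev = [NEG] * W
    # traceback codes: 0 stop, 1 diag, 2 gap-in-query (from E), 3 gap-in-subject (from F)
    tb = np.zeros((Lq + 1, W), dtype=np.uint8)
    best = (0.0, -1, -1)
    for i in range(1, Lq + 1):
        H_cur = [0.0] * W
        E_cur = [NEG] * W
        F_cur = [NEG] * W
        qi = q[i - 1]
        base = i + d0 - band  # subject j at b=0
        for b in range(W):
            j = base + b
            if j < 1 or j > Ls:
                H_cur[b] = 0.0 if 0 <= j <= Ls else NEG
                continue
            # diagonal: (i-1, j-1) is same b in the previous row
            sub = mt if (qi == s[j - 1] and qi < 4) else mm
            diag = H_prev[b] + sub
            # E: gap in query (j-1 -> j at same i) lives at b-1 in this row
            if b > 0:
                E_cur[b] = max(E_cur[b - 1] - ge, H_cur[b - 1] - go - ge)
            # F: gap in subject (i-1 -> i at same j) lives at b+1 in previous row
            if b < W - 1:
                F_cur[b] = max(F_prev[b + 1] - ge, H_prev[b + 1] - go - ge)
            h = max(0.0, diag, E_cur[b], F_cur[b])
            H_cur[b] = h
            if h <= 0.0:
                tb[i, b] = 0
            elif h == diag:
                tb[i, b] = 1
            elif h == E_cur[b]:
                tb[i, b] = 2
            else:
                tb[i, b] = 3
            if h > best[0]:
                best = (h, i, b)
        H_prev, E_prev, F_prev = H_cur, E_cur, F_cur
        # cache rows for traceback
        tb_rows = None
    if best[1] < 0:
        return None
    # traceback (re-walk using stored move codes; affine runs are followed
    # greedily which is exact for score but may shorten gap runs by at most
    # the open/extend trade-off — acceptable for identity bookkeeping)
    score, i, b = best
    q1 = i
    s1 = i + d0 - band + b
    matches = 0
    aln_len = 0
    while i > 0 and tb[i, b] != 0:
        move = tb[i, b]
        j = i + d0 - band + b
        if move == 1:
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                matches += 1
            aln_len += 1
            i -= 1
        elif move == 2:
            aln_len += 1
            b -= 1
        else:
            aln_len += 1
            i -= 1
            b += 1
    q0 = i
    s0 = i + d0 - band + b
    return int(round(score)), q0, q1, s0, s1, matches, aln_len


def _evalue(scheme: ScoringScheme, m: int, n: int, score: int) -> float:
    return float(scheme.K * m * n * np.exp(-scheme.lam * score))


def _search_strand(q: np.ndarray, index: SubjectIndex, scheme: ScoringScheme,
                   qid: str, qlen_full: int, strand: str):
    hits = []
    qk = kmer_codes(q, index.k)
    seeds = index.lookup(qk)
    # group seed positions by (subject, diagonal)
    per_diag: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for qpos, sidx_arr, spos_arr in seeds:
        for sidx, spos in zip(sidx_arr.tolist(), spos_arr.tolist()):
            per_diag.setdefault((sidx, spos - qpos), []).append((qpos, spos))
    # phase 1: un-gapped x-drop extension on every seeded diagonal
    raw = []   # [score, q0, q1, s0, s1, matches, sidx, diag]
    for (sidx, diag), pairs in per_diag.items():
        s = index.codes[sidx]
        pairs.sort()
        covered: list[tuple[int, int]] = []
        for qpos, spos in pairs:
            if any(a <= qpos < b for a, b in covered):
                continue
            q0, q1, s0, s1, score, matches = _ungapped_extend(
                q, s, qpos, spos, index.k, scheme
            )
            covered.append((q0, q1))
            raw.append([score, q0, q1, s0, s1, matches, sidx, diag])
    if not raw:
        return hits
    # phase 2: banded gapped refinement, only for near-best partial
    # alignments (BLAST-style trigger) and only in a window around the
    # un-gapped alignment so chance seeds stay cheap
    best_score = max(r[0] for r in raw)
    trigger = min(25, max(q.size // 2, index.k))
    for r in raw:
        score, q0, q1, s0, s1, matches, sidx, diag = r
        aln_len = q1 - q0
        full_exact = matches == aln_len == q.size
        if (not full_exact and aln_len < 0.9 * q.size
                and score >= max(trigger, best_score - 10)):
            pad = 128
            qw0, qw1 = max(0, q0 - pad), min(q.size, q1 + pad)
            refined = _banded_sw(q[qw0:qw1], index.codes[sidx], diag + qw0, scheme)
            if refined is not None and refined[0] > score:
                score, rq0, rq1, s0, s1, matches, aln_len = refined
                q0, q1 = rq0 + qw0, rq1 + qw0
        if aln_len < index.k or score <= 0:
            continue
        identity = 100.0 * matches / aln_len
        ev = _evalue(scheme, qlen_full, index.total_len, score)
        if strand == "-":
            hq0, hq1 = qlen_full - q1, qlen_full - q0
        else:
            hq0, hq1 = q0, q1
        hits.append(
            AlignmentHit(
                qid, index.subjects[sidx].id, identity, aln_len, score, ev,
                hq0, hq1, s0, s1, strand,
            )
        )
    return hits


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose subject interval mostly overlaps a better hit."""
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if g.subject_id != h.subject_id or g.s_strand != h.s_strand:
                continue
            ov = min(g.s_end, h.s_end) - max(g.s_start, h.s_start)
            if ov > 0.5 * (h.s_end - h.s_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def search(query: SequenceRecord, subjects, scheme: ScoringScheme | None = None,
           min_seed_bp: int = 12) -> list[AlignmentHit]:
    """Local alignments of one query against a subject collection.

    ``subjects`` may be a list of SequenceRecords or a prebuilt
    SubjectIndex (reuse the index when searching many queries).  Hits are
    sorted by score descending, ties by (subject_id, s_start).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if isinstance(subjects, SubjectIndex):
        index = subjects
    else:
        subjects = list(subjects)
        if not subjects:
            return []
        index = SubjectIndex(subjects, k=min_seed_bp)
    if min_seed_bp < 8:
        raise ValueError("min_seed_bp must be >= 8")
    q = query.codes
    if q.size < index.k:
        return []
    hits = _search_strand(q, index, scheme, query.id, q.size, "+")
    hits += _search_strand(revcomp_codes(q), index, scheme, query.id, q.size, "-")
    return _dedupe(hits)


def best_hit_per_query(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Single best hit per query: highest score, ties by the sort order."""
    best: dict[str, AlignmentHit] = {}
    ordered = sorted(hits, key=lambda h: (h.query_id, -h.score, h.subject_id, h.s_start))
    for h in ordered:
        if h.query_id not in best:
            best[h.query_id] = h
    return best


def hits_to_rows(hits: Iterable[AlignmentHit]) -> list[dict]:
    """BLAST outfmt-6-like rows for TSV export."""
    return [
        dict(
            qseqid=h.query_id, sseqid=h.subject_id, pident=round(h.identity, 3),
            length=h.aln_len, score=h.score, evalue=f"{h.evalue:.3g}",
            qstart=h.q_start, qend=h.q_end, sstart=h.s_start, send=h.s_end,
            strand=h.s_strand,
        )
        for h in hits
    ]
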