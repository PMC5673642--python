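"""Fragment-based average nucleotide identity and same-organism dereplication.

Genome A is cut into consecutive 1020 bp fragments; each fragment is
aligned against genome B and its best hit retained when it reaches at
least 30 percent identity over at least 70 percent of the fragment.  ANI
is the mean identity of retained best hits.  Pairs above 98 percent
(strict) are grouped as the same organism by single linkage; the
dereplication uses the maximum of the two directed values, which is the
conservative choice for grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import ScoringScheme, SubjectIndex, search
from .io_core import PipelineThresholds, SequenceRecord

ANI_SEED_BP = 16
MIN_FRAGMENT_IDENTITY = 30.0
MIN_FRAGMENT_COVERAGE = 0.70


@dataclass(frozen=True)
class ANIResult:
    genome_a: str
    genome_b: str
    ani: float | None         # percent; None when no fragment was retained
    n_fragments_used: int
    fraction_aligned: float


def _fragments(seqs: Sequence[SequenceRecord], size: int):
    for s in seqs:
        codes = s.residues
        for i in range(0, len(codes) - size + 1, size):
            yield SequenceRecord(f"{s.id}|f{i}", codes[i : i + size])


def ani(genome_a: Sequence[SequenceRecord], genome_b: Sequence[SequenceRecord],
        thresholds: PipelineThresholds | None = None,
        scheme: ScoringScheme | None = None,
        label_a: str = "A", label_b: str = "B") -> ANIResult:
    """Directed fragment ANI of genome_a against genome_b."""
    th = thresholds or PipelineThresholds()
    scheme = scheme or ScoringScheme()
    size = th.ani_fragment_bp
    len_a = sum(len(s) for s in genome_a)
    len_b = sum(len(s) for s in genome_b)
    if len_a < 2 * size or len_b < 2 * size:
        raise ValueError("both genomes must span at least two fragments")
    index = SubjectIndex(list(genome_b), k=ANI_SEED_BP)
    identities = []
    total = 0
    for frag in _fragments(list(genome_a), size):
        total += 1
        hits = search(frag, index, scheme)
        if not hits:
            continue
        best = hits[0]
        if (best.identity >= MIN_FRAGMENT_IDENTITY
                and best.aln_len >= MIN_FRAGMENT_COVERAGE * size):
            identities.append(best.identity)
    if not identities:
        return ANIResult(label_a, label_b, None, 0, 0.0)
    return ANIResult(
        label_a, label_b, float(np.mean(identities)), len(identities),
        len(identities) / total,
    )


def ani_matrix(bins: Mapping[str, Sequence[SequenceRecord]],
               thresholds: PipelineThresholds | None = None) -> dict:
    """All ordered-pair ANI values: {(a, b): ANIResult}."""
    out = {}
    ids = sorted(bins)
    for a in ids:
        for b in ids:
            if a == b:
                continue
            out[(a, b)] = ani(bins[a], bins[b], thresholds, label_a=a, label_b=b)
    return out


@dataclass
class DereplicationGroup:
    group_id: str
    members: list
    representative: str


def dereplicate_bins(bin_ids: Sequence[str], ani_values: Mapping,
                     threshold: float = 98.0,
                     completeness: Mapping[str, float] | None = None,
                     lengths: Mapping[str, float] | None = None
                     ) -> list[DereplicationGroup]:
    """Single-linkage grouping of bins with ANI > threshold (strict).

    ``ani_values`` maps ordered pairs to ANIResult or a float; the maximum
    of the two directions is used.  The representative of each group is the
    most complete bin, ties broken by larger length then lexicographic id.
    """
    completeness = completeness or {}
    lengths = lengths or {}
    parent = {b: b for b in bin_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def value(pair):
        v = ani_values.get(pair)
        if v is None:
            return None
        return v.ani if isinstance(v, ANIResult) else float(v)

    ids = sorted(bin_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            vals = [v for v in (value((a, b)), value((b, a))) if v is not None]
            if vals and max(vals) > threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list] = {}
    for b in ids:
        groups.setdefault(find(b), []).append(b)
    out = []
    for i, members in enumerate(sorted(groups.values(), key=lambda m: m[0]), 1):
        rep = min(
            members,
            key=lambda b: (-completeness.get(b, 0.0), -lengths.get(b, 0.0), b),
        )
        out.append(DereplicationGroup(f"org{i:02d}", sorted(members), rep))
    return out
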