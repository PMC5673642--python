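"""Per-bin genome quality and streamlining metrics.

Completeness and contamination come from a single-copy marker census:
completeness is the percentage of expected markers present at least once,
contamination the percentage of surplus copies.  The estimated genome size
contamination-corrects the assembled length and scales it up by the
completeness:

    est_size = length * (1 - contamination/100) / (completeness/100)

Streamlining indicators are the coding density (union of coding intervals
over total length) and the median intergenic spacer between consecutive
genes on the same contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import GeneCall, SequenceRecord


@dataclass(frozen=True)
class MarkerSet:
    """Markers expected in exactly one copy in the lineage."""

    marker_ids: tuple

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        if len(self.marker_ids) < 20:
            import warnings

            warnings.warn("marker sets below 20 genes give unstable estimates")

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass
class MAGRecord:
    """One summary-table row for a metagenome-assembled genome."""

    bin_id: str
    n_cds: int
    length_mb: float
    gc: float
    median_spacer_bp: float | None
    coding_density: float
    completeness: float
    contamination: float
    est_size_mb: float | None
    origin: str = ""
    class_label: str = ""


def completeness_contamination(marker_copies: Mapping[str, int], markers: MarkerSet
                               ) -> tuple[float, float]:
    """Percent of markers present, and percent of surplus marker copies.

    ``marker_copies`` maps marker id -> copy count observed in the bin
    (markers absent from the mapping count as 0 copies).
    """
    if len(markers) == 0:
        raise ValueError("empty marker set")
    present = sum(1 for m in markers.marker_ids if marker_copies.get(m, 0) >= 1)
    surplus = sum(max(0, marker_copies.get(m, 0) - 1) for m in markers.marker_ids)
    n = len(markers)
    return 100.0 * present / n, 100.0 * surplus / n


def estimated_genome_size(length_mb: float, completeness: float,
                          contamination: float) -> float:
    """Contamination-corrected, completeness-scaled genome size in Mb."""
    if completeness <= 0:
        raise ValueError("undefined: completeness must be > 0")
    return length_mb * (1.0 - contamination / 100.0) / (completeness / 100.0)


def coding_density(contigs: Sequence[SequenceRecord],
                   gene_calls: Sequence[GeneCall]) -> float:
    """Percent of contig sequence covered by the union of coding intervals."""
    lengths = {c.id: len(c) for c in contigs}
    total = sum(lengths.values())
    if total == 0:
        raise ValueError("no contig sequence")
    by_contig: dict[str, list] = {}
    for g in gene_calls:
        if g.contig_id not in lengths:
            continue
        if g.end > lengths[g.contig_id]:
            raise ValueError(f"{g.gene_id}: gene extends beyond contig end")
        by_contig.setdefault(g.contig_id, []).append((g.start, g.end))
    covered = 0
    for ivs in by_contig.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return 100.0 * covered / total


def median_intergenic_spacer(gene_calls: Sequence[GeneCall]) -> float | None:
    """Median gap between consecutive same-contig genes, overlaps clamped to 0.

    Returns None when no contig carries two or more genes.
    """
    by_contig: dict[str, list] = {}
    for g in gene_calls:
        by_contig.setdefault(g.contig_id, []).append(g)
    spacers = []
    for genes in by_contig.values():
        genes.sort(key=lambda g: g.start)
        for prev, nxt in zip(genes, genes[1:]):
            spacers.append(max(0, nxt.start - prev.end))
    if not spacers:
        return None
    return float(np.median(spacers))


def gc_content(seqs: Iterable[SequenceRecord]) -> float:
    """Percent G+C over non-N bases."""
    gc = at = 0
    for s in seqs:
        codes = s.codes
        gc += int(np.count_nonzero((codes == 1) | (codes == 2)))
        at += int(np.count_nonzero((codes == 0) | (codes == 3)))
    if gc + at == 0:
        raise ValueError("no non-N bases")
    return 100.0 * gc / (gc + at)


def marker_occurrences(contig_ids: Iterable[str], marker_calls: Sequence[GeneCall],
                       markers: MarkerSet) -> dict:
    """Copy counts of each marker among gene calls on the given contigs.

    Marker gene ids are expected to end in ``|<marker_id>``.
    """
    contig_ids = set(contig_ids)
    copies = {m: 0 for m in markers.marker_ids}
    for call in marker_calls:
        if call.contig_id not in contig_ids:
            continue
        mid = call.gene_id.rsplit("|", 1)[-1]
        if mid in copies:
            copies[mid] += 1
    return copies


def build_mag_record(bin_id: str, contigs: Sequence[SequenceRecord],
                     gene_calls: Sequence[GeneCall],
                     marker_copies: Mapping[str, int], markers: MarkerSet,
                     origin: str = "", class_label: str = "") -> MAGRecord:
    """Assemble one summary-table row from a bin's contigs and annotations."""
    ids = {c.id for c in contigs}
    genes = [g for g in gene_calls if g.contig_id in ids]
    length_mb = sum(len(c) for c in contigs) / 1e6
    comp, cont = completeness_contamination(marker_copies, markers)
    est = round(estimated_genome_size(length_mb, comp, cont), 2) if comp > 0 else None
    return MAGRecord(
        bin_id=bin_id,
        n_cds=len(genes),
        length_mb=round(length_mb, 2),
        gc=round(gc_content(contigs), 2),
        median_spacer_bp=median_intergenic_spacer(genes),
        coding_density=round(coding_density(contigs, genes), 2),
        completeness=round(comp, 2),
        contamination=round(cont, 2),
        est_size_mb=est,
        origin=origin,
        class_label=class_label,
    )
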