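"""Sequence/annotation I/O, coordinate conventions, and pipeline thresholds.

All coordinates inside the package are 0-based half-open; GFF3 is 1-based
inclusive and is converted exactly once, here, at the file boundary.
Sequence files may be gzip-compressed (detected by the ``.gz`` suffix).
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._codes import BASES, encode

logger = logging.getLogger("limnobin")

_ALPHABET = set(BASES)


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}; the pipeline's universal currency."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        up = self.residues.upper()
        bad = next((i for i, ch in enumerate(up) if ch not in _ALPHABET), None)
        if bad is not None:
            raise ValueError(f"{self.id}: invalid residue {up[bad]!r} at position {bad}")
        object.__setattr__(self, "residues", up)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self):
        return encode(self.residues)


@dataclass(frozen=True)
class GeneCall:
    """A gene interval on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PipelineThresholds:
    """Every numeric cutoff of the pipeline, in one auditable place.

    Comparison senses follow the stage contracts: the gene-vote fraction and
    recruitment identity are strict inequalities; the classification
    identity/length and recruitment length/e-value are inclusive; ANI
    same-organism grouping is strict.
    """

    min_contig_bp: int = 10000
    vote_fraction: float = 0.60          # strict >
    derep_identity: float = 0.90
    candidate_evalue: float = 1e-5       # strict <
    classify_identity: float = 0.80      # >=
    classify_alnlen_bp: int = 90         # >=
    recruit_identity: float = 0.95       # strict >
    recruit_alnlen_bp: int = 50          # >=
    recruit_evalue: float = 1e-5         # <=
    ani_same_organism: float = 98.0      # strict >, percent
    ani_fragment_bp: int = 1020

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineThresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown threshold keys: {sorted(bad)}")
        return cls(**d)

    def header_lines(self) -> list[str]:
        """Comment lines serialised into every report header."""
        return [f"# {k}={v}" for k, v in self.as_dict().items()]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    with _open_text(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return "fasta"
    if first.startswith("@"):
        return "fastq"
    raise ValueError(f"{path}: cannot detect sequence format from first line {first[:20]!r}")


def read_sequences(path, format: str = "auto") -> list[SequenceRecord]:
    """Read FASTA/FASTQ into SequenceRecords, validating ids and residues."""
    path = Path(path)
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, format):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            try:
                records.append(SequenceRecord(rec.id, str(rec.seq), desc))
            except ValueError as e:
                raise ValueError(f"{path}: {e}") from None
    return records


def write_sequences(records: Iterable[SequenceRecord], path, format: str = "fasta") -> None:
    bio = (
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    )
    with _open_text(path, "wt") as fh:
        if format == "fastq":
            def with_qual(rs):
                for r in rs:
                    r.letter_annotations["phred_quality"] = [40] * len(r.seq)
                    yield r
            SeqIO.write(with_qual(bio), fh, "fastq")
        else:
            SeqIO.write(bio, fh, "fasta")


def read_gene_calls(path) -> list[GeneCall]:
    """Read CDS features from GFF3 into 0-based half-open GeneCalls.

    The optional ``taxon=`` attribute is honoured; gene ids come from the
    ``ID=`` attribute or are synthesised as contig:start-end.
    """
    calls: list[GeneCall] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame = parts[:8]
            if ftype != "CDS":
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand required for CDS")
            attrs = {}
            if len(parts) > 8 and parts[8] != ".":
                for kv in parts[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k.strip()] = v.strip()
            gene_id = attrs.get("ID", f"{contig}:{start1 - 1}-{end1}")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            calls.append(
                GeneCall(contig, start1 - 1, end1, strand, gene_id, attrs.get("taxon"))
            )
    return calls


def write_gene_calls(calls: Iterable[GeneCall], path, source: str = "limnobin") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in calls:
            attrs = f"ID={g.gene_id}"
            if g.taxon:
                attrs += f";taxon={g.taxon}"
            fh.write(
                f"{g.contig_id}\t{source}\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def write_table(rows: Sequence, path, float_fmt: str = "%.2f",
                thresholds: PipelineThresholds | None = None) -> None:
    """Write homogeneous dataclass/dict rows as a TSV with a header line.

    Floats are printed at fixed precision (two decimals for Mb / percent
    columns by default).  If thresholds are given they are echoed as
    ``#``-prefixed header comments.
    """
    rows = list(rows)
    if rows and dataclasses.is_dataclass(rows[0]):
        dicts = [dataclasses.asdict(r) for r in rows]
    else:
        dicts = [dict(r) for r in rows]
    if dicts:
        cols = list(dicts[0].keys())
        if any(list(d.keys()) != cols for d in dicts):
            raise ValueError("rows are not homogeneous")
    else:
        cols = []
    with _open_text(path, "wt") as fh:
        if thresholds is not None:
            for line in thresholds.header_lines():
                fh.write(line + "\n")
        fh.write("\t".join(cols) + "\n")
        for d in dicts:
            cells = []
            for v in d.values():
                if isinstance(v, bool):
                    cells.append(str(v))
                elif isinstance(v, float):
                    cells.append(float_fmt % v)
                elif v is None:
                    cells.append("NA")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_config(path) -> dict:
    with _open_text(path) as fh:
        text = fh.read()
    cfg = yaml.safe_load(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        # fall back to flat key=value lines
        cfg = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line not key=value: {line!r}")
            k, v = line.split("=", 1)
            cfg[k.strip()] = yaml.safe_load(v.strip())
    return cfg


def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0
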