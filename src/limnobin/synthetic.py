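"""Ground-truthed synthetic communities for the binning/ANI/recruitment/16S stages.

Each genome is drawn from its own order-2 Markov chain (seeded per genome),
which gives genomes genuine, distinct tetranucleotide signatures — the
signal composition-based binning exploits — without copying real genomes.
A GC tilt is solved numerically so the chain's stationary GC content hits
the requested target.  Genomes carry planted single-copy marker genes,
ordinary protein-coding genes with (imperfect) taxon labels, and 16S genes
derived from a labelled reference set.  Reads are single-ended with i.i.d.
substitution errors; the mutation model is substitution-only so true
nucleotide identity between genome pairs is analytic (1 - mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._codes import _COMP as _COMP_LOOKUP
from ._codes import decode, encode
from .io_core import GeneCall, SequenceRecord

MAX_READS_PER_SAMPLE = 10_000_000
NOISE_TAXON = "noise"


@dataclass(frozen=True)
class GenomeSpec:
    """Design of one synthetic source genome."""

    genome_id: str
    length_bp: int
    gc_target: float
    composition_seed: int
    taxon: str
    n_16s_copies: int = 0
    marker_ids_planted: tuple = ()
    # ordinary-gene planting (drives taxon votes, coding density, spacers)
    gene_mean_len: int = 800
    gene_spacer_mean: int = 120
    p_gene_on_taxon: float = 0.8
    p_gene_unlabeled: float = 0.15
    ssu_mutation: float = 0.01
    # Dirichlet concentration of the transition rows; 1 gives strongly
    # genome-specific (repetitive) composition, large values approach
    # uniform DNA — used for the aggregate background
    composition_concentration: float = 1.0

    def __post_init__(self) -> None:
        if not (0.2 <= self.gc_target <= 0.8):
            raise ValueError("gc_target must be in [0.2, 0.8]")
        if self.length_bp < 1000:
            raise ValueError("genome length must be >= 1 kb")


@dataclass
class CommunityDesign:
    """Multi-sample shotgun design: who is sequenced how deep, and how noisy."""

    genome_specs: list
    coverage: np.ndarray          # genomes x samples, x-fold depth
    read_length_bp: int = 100
    per_base_error: float = 0.0
    metagenome_target_gbp: float = 0.0   # pad each sample with noise reads up to this
    seed: int = 0
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        self.coverage = np.atleast_2d(np.asarray(self.coverage, dtype=float))
        if (self.coverage < 0).any():
            raise ValueError("coverages must be >= 0")
        if not (0.0 <= self.per_base_error <= 0.1):
            raise ValueError("per_base_error must be in [0, 0.1]")
        if self.sample_ids is None:
            self.sample_ids = [f"S{j+1}" for j in range(self.coverage.shape[1])]


@dataclass
class GroundTruth:
    """Truth labels for every simulated object."""

    genome_order: list = field(default_factory=list)
    contig_to_genome: dict = field(default_factory=dict)
    read_sources: dict = field(default_factory=dict)   # sample_id -> genome index per read
    gene_to_taxon: dict = field(default_factory=dict)  # gene_id -> taxon or None
    gene_calls: list = field(default_factory=list)
    marker_calls: list = field(default_factory=list)
    ssu_intervals: list = field(default_factory=list)  # (genome_id, start, end, taxon)
    true_mutation: dict = field(default_factory=dict)  # (id_a, id_b) -> mu


class ReadSet:
    """A sample's reads as one uint8 code matrix (rows padded with N if ragged)."""

    def __init__(self, sample_id: str, codes: np.ndarray, lengths: np.ndarray | None = None):
        self.sample_id = sample_id
        self.codes = np.ascontiguousarray(codes, dtype=np.uint8)
        if lengths is None:
            lengths = np.full(self.codes.shape[0], self.codes.shape[1], dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    def read_id(self, i: int) -> str:
        ids = getattr(self, "_ids", None)
        return ids[i] if ids is not None else f"{self.sample_id}_r{i}"

    def record(self, i: int) -> SequenceRecord:
        return SequenceRecord(self.read_id(i), decode(self.codes[i, : self.lengths[i]]))

    def __iter__(self):
        return (self.record(i) for i in range(len(self)))

    @classmethod
    def from_records(cls, sample_id: str, records: Sequence[SequenceRecord]) -> "ReadSet":
        lengths = np.array([len(r) for r in records], dtype=np.int64)
        width = int(lengths.max()) if len(records) else 0
        codes = np.full((len(records), width), 4, dtype=np.uint8)  # pad with N
        for i, r in enumerate(records):
            codes[i, : len(r)] = r.codes
        rs = cls(sample_id, codes, lengths)
        rs._ids = [r.id for r in records]
        return rs


# ---------------------------------------------------------------------------
# order-2 Markov composition


def _stationary_gc(trans: np.ndarray) -> float:
    """Stationary GC of the dinucleotide chain induced by P(c | a,b)."""
    T = np.zeros((16, 16))
    for a in range(4):
        for b in range(4):
            for c in range(4):
                T[4 * a + b, 4 * b + c] = trans[a, b, c]
    pi = np.full(16, 1 / 16)
    for _ in range(200):
        pi = pi @ T
    pi /= pi.sum()
    return float(pi.reshape(4, 4)[:, [1, 2]].sum())  # second base is C or G


def _tilted(trans: np.ndarray, x: float) -> np.ndarray:
    w = np.array([1.0, x, x, 1.0])
    t = trans * w[None, None, :]
    return t / t.sum(axis=2, keepdims=True)


def composition_matrix(gc_target: float, composition_seed: int,
                       concentration: float = 1.0) -> np.ndarray:
    """Per-genome order-2 transition probabilities with stationary GC = target."""
    rng = np.random.default_rng(composition_seed)
    base = rng.dirichlet(np.full(4, concentration), size=(4, 4))
    lo, hi = -6.0, 6.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _stationary_gc(_tilted(base, np.exp(mid))) < gc_target:
            lo = mid
        else:
            hi = mid
    return _tilted(base, np.exp(0.5 * (lo + hi)))


def _sample_chain(trans: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(trans.reshape(16, 4), axis=1)
    cum_list = cum.tolist()
    u = rng.random(n)
    out = np.empty(n, dtype=np.uint8)
    a = int(rng.integers(4))
    b = int(rng.integers(4))
    out[0], out[1] = a, b
    for i in range(2, n):
        row = cum_list[4 * a + b]
        r = u[i]
        c = 0
        while row[c] < r:
            c += 1
        out[i] = c
        a, b = b, c
    return out


def _place_intervals(rng: np.random.Generator, length: int, sizes: list[int],
                     occupied: list[tuple[int, int]] | None = None) -> list[tuple[int, int]]:
    """Greedy non-overlapping random placement of intervals on [0, length)."""
    placed = list(occupied or [])
    out = []
    for size in sizes:
        if size > length:
            raise ValueError(f"planted feature of {size} bp exceeds genome length {length}")
        for _ in range(1000):
            start = int(rng.integers(0, length - size + 1))
            iv = (start, start + size)
            if all(iv[1] <= a or iv[0] >= b for a, b in placed):
                placed.append(iv)
                out.append(iv)
                break
        else:
            raise ValueError("could not place planted features without overlap")
    return out


def simulate_genome(spec: GenomeSpec, ref_db=None, truth: GroundTruth | None = None
                    ) -> tuple[SequenceRecord, GroundTruth]:
    """Simulate one genome; plant 16S copies, markers, and ordinary genes.

    Deterministic in ``spec.composition_seed``.  16S copies are taken from
    ``ref_db`` (a ssu.ReferenceDB) for ``spec.taxon`` and mutated at
    ``spec.ssu_mutation`` (<= 2 percent) before splicing.
    """
    if truth is None:
        truth = GroundTruth()
    rng = np.random.default_rng(spec.composition_seed)
    trans = composition_matrix(spec.gc_target, spec.composition_seed,
                               spec.composition_concentration)
    codes = _sample_chain(trans, spec.length_bp, rng)

    gid = spec.genome_id
    # 16S copies
    ssu_sizes = []
    ssu_seqs = []
    if spec.n_16s_copies > 0:
        if ref_db is None:
            raise ValueError(f"{gid}: 16S copies requested but no reference db given")
        refs = [r for r in ref_db.records if ref_db.taxon_of[r.id] == spec.taxon]
        if not refs:
            raise ValueError(f"{gid}: reference db has no taxon {spec.taxon!r}")
        for _ in range(spec.n_16s_copies):
            template = refs[int(rng.integers(len(refs)))]
            mutated = mutate_codes(template.codes, spec.ssu_mutation, rng)
            ssu_seqs.append(mutated)
            ssu_sizes.append(mutated.size)
    marker_len = 800
    marker_sizes = [marker_len] * len(spec.marker_ids_planted)
    spots = _place_intervals(rng, spec.length_bp, ssu_sizes + marker_sizes)
    ssu_spots = spots[: len(ssu_sizes)]
    marker_spots = spots[len(ssu_sizes):]
    for (s, e), seq in zip(ssu_spots, ssu_seqs):
        codes[s:e] = seq
        truth.ssu_intervals.append((gid, s, e, spec.taxon))
    for (s, e), mid in zip(marker_spots, spec.marker_ids_planted):
        call = GeneCall(gid, s, e, "+", f"{gid}|{mid}", spec.taxon)
        truth.marker_calls.append(call)

    # ordinary genes with imperfect taxon labels
    pos = 0
    i = 0
    while True:
        start = pos + int(rng.geometric(1.0 / spec.gene_spacer_mean))
        glen = max(200, int(rng.normal(spec.gene_mean_len, spec.gene_mean_len / 4)))
        if start + glen > spec.length_bp:
            break
        u = rng.random()
        if u < spec.p_gene_on_taxon:
            taxon = spec.taxon
        elif u < spec.p_gene_on_taxon + spec.p_gene_unlabeled:
            taxon = None
        else:
            taxon = "offtarget"
        strand = "+" if rng.random() < 0.5 else "-"
        call = GeneCall(gid, start, start + glen, strand, f"{gid}_g{i}", taxon)
        truth.gene_calls.append(call)
        truth.gene_to_taxon[call.gene_id] = taxon
        pos = start + glen
        i += 1

    truth.genome_order.append(gid)
    return SequenceRecord(gid, decode(codes), f"taxon={spec.taxon}"), truth


def mutate_codes(codes: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    if mu == 0:
        return out
    sites = np.nonzero((rng.random(codes.size) < mu) & (codes < 4))[0]
    out[sites] = (out[sites] + rng.integers(1, 4, sites.size).astype(np.uint8)) % 4
    return out


def mutate_genome(genome: SequenceRecord, mu: float, seed: int) -> SequenceRecord:
    """Substitution-only point mutation at per-site rate mu (no indels)."""
    if not (0.0 <= mu <= 0.3):
        raise ValueError("mu must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    out = mutate_codes(genome.codes, mu, rng)
    return SequenceRecord(f"{genome.id}_mu{mu:g}", decode(out), genome.description)


def fragment_genome(genome: SequenceRecord, length_law: dict, seed: int,
                    truth: GroundTruth | None = None
                    ) -> tuple[list[SequenceRecord], GroundTruth]:
    """Tile a genome into non-overlapping contigs with shifted-geometric lengths.

    Fragment length = min_bp + Geometric(p) - 1 with mean ``mean_bp``; the
    trailing remainder is absorbed into the final fragment so lengths
    conserve the genome exactly and every fragment is >= min_bp.
    """
    min_bp, mean_bp = int(length_law["min_bp"]), int(length_law["mean_bp"])
    if mean_bp < min_bp:
        raise ValueError("mean_bp must be >= min_bp")
    if truth is None:
        truth = GroundTruth()
    rng = np.random.default_rng(seed)
    p = 1.0 / (mean_bp - min_bp + 1)
    cuts = []
    pos = 0
    L = len(genome)
    while True:
        frag = min_bp + int(rng.geometric(p)) - 1
        if L - pos - frag < min_bp:
            cuts.append((pos, L))
            break
        cuts.append((pos, pos + frag))
        pos += frag
    contigs = []
    for i, (s, e) in enumerate(cuts):
        cid = f"{genome.id}_c{i}"
        contigs.append(SequenceRecord(cid, genome.residues[s:e], f"source={genome.id}:{s}-{e}"))
        truth.contig_to_genome[cid] = genome.id

    # re-map planted annotations from genome to contig coordinates;
    # boundary-spanning features are dropped (broken genes go unannotated)
    def remap(calls):
        out = []
        for g in calls:
            if g.contig_id != genome.id:
                out.append(g)
                continue
            for i, (s, e) in enumerate(cuts):
                if s <= g.start and g.end <= e:
                    out.append(GeneCall(f"{genome.id}_c{i}", g.start - s, g.end - s,
                                        g.strand, g.gene_id, g.taxon))
                    break
        return out

    truth.gene_calls = remap(truth.gene_calls)
    truth.marker_calls = remap(truth.marker_calls)
    ssu_out = []
    for gid, s0, e0, taxon in truth.ssu_intervals:
        if gid != genome.id:
            ssu_out.append((gid, s0, e0, taxon))
            continue
        for i, (s, e) in enumerate(cuts):
            if s <= s0 and e0 <= e:
                ssu_out.append((f"{genome.id}_c{i}", s0 - s, e0 - s, taxon))
                break
    truth.ssu_intervals = ssu_out
    return contigs, truth


def simulate_reads(design: CommunityDesign, genomes: Sequence[SequenceRecord],
                   background: SequenceRecord | None = None,
                   truth: GroundTruth | None = None
                   ) -> tuple[dict, GroundTruth]:
    """Simulate per-sample shotgun read sets with uniform starts and i.i.d. errors.

    Read count for genome g in sample s is round(coverage[g,s] * len(g) /
    read_length).  When ``metagenome_target_gbp`` > 0, filler reads from the
    ``background`` genome pad each sample to that many Gbp of sequence.
    """
    if truth is None:
        truth = GroundTruth()
    rl = design.read_length_bp
    cov = design.coverage
    if cov.shape[0] != len(genomes):
        raise ValueError("coverage rows must match number of genomes")
    rng = np.random.default_rng(design.seed)
    sources = list(genomes)
    source_codes = [g.codes for g in sources]
    bg_index = None
    if background is not None:
        bg_index = len(sources)
        sources.append(background)
        source_codes.append(background.codes)
    out: dict[str, ReadSet] = {}
    genome_ids = [g.id for g in sources]
    for j, sample_id in enumerate(design.sample_ids):
        counts = [int(round(cov[g, j] * len(sources[g]) / rl)) for g in range(len(genomes))]
        planted_bases = sum(c * rl for c in counts)
        n_bg = 0
        if design.metagenome_target_gbp > 0:
            target = int(round(design.metagenome_target_gbp * 1e9))
            if target < planted_bases:
                raise ValueError("metagenome target smaller than planted reads")
            if background is None:
                raise ValueError("padding requested but no background genome given")
            n_bg = (target - planted_bases) // rl
        n_total = sum(counts) + n_bg
        if n_total > MAX_READS_PER_SAMPLE:
            raise ValueError(
                f"sample {sample_id}: {n_total} reads exceeds the "
                f"{MAX_READS_PER_SAMPLE} desk-scale guard"
            )
        codes = np.empty((n_total, rl), dtype=np.uint8)
        src = np.empty(n_total, dtype=np.uint16)
        row = 0
        plan = list(zip(range(len(counts)), counts))
        if n_bg:
            plan.append((bg_index, n_bg))
        for g, n in plan:
            gcodes = source_codes[g]
            if n == 0:
                continue
            if len(gcodes) < rl:
                raise ValueError(f"{genome_ids[g]}: genome shorter than read length")
            done = 0
            while done < n:
                chunk = min(200_000, n - done)
                starts = rng.integers(0, gcodes.size - rl + 1, chunk)
                block = gcodes[starts[:, None] + np.arange(rl)]
                flip = rng.random(chunk) < 0.5   # reads come off both strands
                block[flip] = _COMP_LOOKUP[block[flip]][:, ::-1]
                if design.per_base_error > 0:
                    err = rng.random(block.shape) < design.per_base_error
                    err &= block < 4
                    shifts = rng.integers(1, 4, int(err.sum())).astype(np.uint8)
                    block[err] = (block[err] + shifts) % 4
                codes[row : row + chunk] = block
                src[row : row + chunk] = g
                row += chunk
                done += chunk
        out[sample_id] = ReadSet(sample_id, codes)
        truth.read_sources[sample_id] = src
    truth.genome_order = genome_ids
    return out, truth


# ---------------------------------------------------------------------------
# 16S reference set and end-to-end community bundle


def simulate_reference_db(n_taxa: int = 8, refs_per_taxon: int = 8,
                          length: int = 1500, taxon_divergence: float = 0.10,
                          within_divergence: float = 0.02, seed: int = 0,
                          taxa: Sequence[str] | None = None):
    """A labelled synthetic 16S reference set.

    All references descend from one random ancestor gene; each taxon's type
    sequence diverges from it at ``taxon_divergence`` substitutions per
    site, and references within a taxon scatter around the type at
    ``within_divergence``.  Returns a ssu.ReferenceDB.
    """
    from .ssu import ReferenceDB

    rng = np.random.default_rng(seed)
    if taxa is None:
        taxa = [f"T{i+1}" for i in range(n_taxa)]
    else:
        taxa = list(taxa)
        while len(taxa) < n_taxa:
            taxa.append(f"T{len(taxa)+1}")
    ancestor = rng.integers(0, 4, length).astype(np.uint8)
    records, taxon_of = [], {}
    for taxon in taxa:
        type_seq = mutate_codes(ancestor, taxon_divergence, rng)
        for j in range(refs_per_taxon):
            ref = mutate_codes(type_seq, within_divergence, rng)
            rid = f"ref_{taxon}_{j+1}"
            records.append(SequenceRecord(rid, decode(ref), f"taxon={taxon}"))
            taxon_of[rid] = taxon
    return ReferenceDB(records, taxon_of)


def simulate_ssu_read_mixture(db, n_reads: int, ssu_fraction: float,
                              target_taxon: str, target_fraction_of_ssu: float,
                              read_length: int = 150, per_base_error: float = 0.02,
                              gene_divergence: float = 0.01, seed: int = 0):
    """Reads for the 16S cascade: planted 16S fragments in a random background.

    ``ssu_fraction`` of the reads derive from 16S genes (reference sequences
    mutated at ``gene_divergence``, emulating genome-resident copies);
    ``target_fraction_of_ssu`` of those come from the target taxon, the rest
    uniformly from the other taxa.  Background reads are uniform random DNA.
    Returns (records, true_taxon_per_read) where background reads are
    labelled None.
    """
    rng = np.random.default_rng(seed)
    n_ssu = int(round(n_reads * ssu_fraction))
    n_target = int(round(n_ssu * target_fraction_of_ssu))
    by_taxon: dict[str, list] = {}
    for r in db.records:
        by_taxon.setdefault(db.taxon_of[r.id], []).append(r)
    others = sorted(t for t in by_taxon if t != target_taxon)
    records, labels = [], []
    for i in range(n_reads):
        if i < n_target:
            taxon = target_taxon
        elif i < n_ssu:
            taxon = others[int(rng.integers(len(others)))]
        else:
            taxon = None
        if taxon is None:
            codes = rng.integers(0, 4, read_length).astype(np.uint8)
        else:
            refs = by_taxon[taxon]
            template = refs[int(rng.integers(len(refs)))].codes
            gene = mutate_codes(template, gene_divergence, rng)
            start = int(rng.integers(0, gene.size - read_length + 1))
            codes = mutate_codes(gene[start : start + read_length], per_base_error, rng)
        records.append(SequenceRecord(f"mix_r{i}", decode(codes)))
        labels.append(taxon)
    order = rng.permutation(n_reads)
    return [records[i] for i in order], [labels[i] for i in order]


@dataclass
class CommunityBundle:
    design: CommunityDesign
    ref_db: object
    genomes: list
    background: SequenceRecord | None
    contigs: list
    reads: dict
    truth: GroundTruth


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def simulate_community(design: CommunityDesign, min_contig_bp: int = 10000,
                       mean_contig_bp: int = 25000,
                       background_length_bp: int = 200_000,
                       ref_db=None) -> CommunityBundle:
    """Run the whole generator: reference db, genomes, contigs, reads, truth."""
    truth = GroundTruth()
    taxa = sorted({s.taxon for s in design.genome_specs})
    if ref_db is None and any(s.n_16s_copies > 0 for s in design.genome_specs):
        ref_db = simulate_reference_db(
            n_taxa=max(8, len(taxa)), taxa=taxa,
            seed=_stage_seed(design.seed, "refdb"),
        )
    genomes = []
    for spec in design.genome_specs:
        g, truth = simulate_genome(spec, ref_db, truth)
        genomes.append(g)
    bg_spec = GenomeSpec(
        "noise", background_length_bp, 0.5,
        _stage_seed(design.seed, "background"), NOISE_TAXON,
        composition_concentration=50.0,   # aggregate of many organisms
    )
    background, truth = simulate_genome(bg_spec, None, truth)
    contigs = []
    for g in genomes:
        cs, truth = fragment_genome(
            g, {"min_bp": min_contig_bp, "mean_bp": mean_contig_bp},
            _stage_seed(design.seed, f"frag:{g.id}"), truth,
        )
        contigs.extend(cs)
    reads, truth = simulate_reads(design, genomes, background, truth)
    return CommunityBundle(design, ref_db, genomes, background, contigs, reads, truth)


def tnf_l1_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """L1 distance between canonical tetranucleotide profiles (binnability check)."""
    from .binning import tnf_profile

    fa = tnf_profile(a).freqs
    fb = tnf_profile(b).freqs
    return float(np.abs(fa - fb).sum())
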