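# Methods

`limnobin` implements a genome-resolved metagenomics workflow for
freshwater communities — 16S rRNA read screening, taxonomy-guided
composition/coverage binning, genome quality and streamlining metrics,
ANI dereplication, fragment-recruitment abundance, and FISH census
arithmetic — together with a ground-truthed community simulator that the
test suite exercises the whole pipeline on.  This note records the models,
the defaults and why they were chosen, and what the synthetic benchmarks
do and do not demonstrate.

## Pipeline thresholds

Every numeric cutoff lives in `PipelineThresholds` and is echoed into the
header of every report the pipeline writes.  The comparison senses are part
of the contract:

| cutoff | value | sense |
| --- | --- | --- |
| contig length for binning | 10 000 bp | strict > |
| per-contig gene vote for the target phylum | 0.60 | strict > |
| reference dereplication identity | 90 % | ≥, over ≥80 % of the record |
| 16S candidate e-value | 1e-5 | strict < |
| 16S classification identity / length | 80 % / 90 bp | both ≥ |
| recruitment length / identity / e-value | 50 bp / 95 % / 1e-5 | ≥ / strict > / ≤ |
| same-organism ANI | 98 % | strict > |
| ANI fragment size | 1020 bp | fixed |

## Synthetic communities

The generator's job is to produce data with exactly the statistical
structure the analysis stages assume, plus complete truth labels.

**Genome composition.** Each genome is sampled from its own order-2 Markov
chain.  The 16 transition rows are Dirichlet draws seeded per genome, so
two genomes with different composition seeds have genuinely different
tetranucleotide signatures (L1 distance between profiles ≫ 0.05) — the
signal composition binning exploits — without copying any real genome.  A
GC tilt factor is applied to the transition rows and solved by bisection on
the stationary distribution of the induced dinucleotide chain, so the
chain's stationary GC equals the requested target; at 1 Mb the realised GC
is within ±0.01 of target.  The Dirichlet concentration is a parameter:
the default 1.0 yields strongly genome-specific (locally repetitive)
composition, while the aggregate "noise" background genome uses
concentration 50, approaching uniform DNA — an aggregate of many unrelated
organisms has far higher sequence entropy than any single genome.

**Planted features.** Genomes carry (i) single-copy marker genes recorded
as gene calls (their sequence content is irrelevant to the marker census,
which counts occurrences); (ii) 16S genes spliced in from a labelled
synthetic reference set, mutated at ≤2 % so genome copies differ from the
reference as real rRNA operons do; (iii) ordinary protein-coding genes
tiled along the genome (mean length 800 bp, mean spacer 120 bp,
i.e. ~85 % coding density, typical of streamlined bacteria) whose taxonomy
labels are deliberately imperfect: 80 % on-taxon, 15 % unlabelled, 5 %
off-target, so the >60 % vote rule is tested under realistic annotation
noise.

**16S reference set.** All references descend from one random ancestor
gene; taxa diverge at 10 % substitutions per site and references within a
taxon scatter at 2 %.  That places within-taxon read identities in the
mid-90s and between-taxon identities near 80 %, bracketing the ≥80 %
classification threshold the way a real high-level-taxon reference set
does.

**Mutation model.** `mutate_genome` applies i.i.d. substitutions only — no
indels.  This is a deliberate simplification: it makes the true nucleotide
identity between a genome and its mutant analytic (1 − μ), which is what
lets the ANI stage be tested for parameter recovery rather than against a
second heuristic.

**Contigs.** Genomes are tiled into non-overlapping fragments with
shifted-geometric lengths (min 10 kb, mean 25 kb by default); the trailing
remainder is absorbed into the last fragment so lengths conserve exactly.
Planted annotations are remapped to contig coordinates;
boundary-spanning genes are dropped, as fragmented genes usually go
unannotated in real assemblies.

**Reads.** Single-end reads of fixed length, uniform start positions,
random strand, i.i.d. substitution errors.  Read count per genome and
sample is round(coverage × genome length / read length).  Filler reads
from the background genome pad a sample to a requested total (Gbp);
a guard refuses designs over 10⁷ reads per sample.  Single-end suffices
because every downstream quantity (RPKG, coverage, votes) counts reads or
aligned bases, not pairs.

**What the generator does not emulate** — and therefore what passing tests
do not demonstrate about field data: indels and structural variation,
chimeric contigs, strain mixtures within a population, sequencing quality
score models, GC-dependent coverage bias, conserved-domain convergence
between unrelated genomes, and realistic rRNA secondary structure.  The
synthetic benchmarks establish that the implementation of each rule is
correct and that the stages compose; they do not re-establish the field
observations themselves.

## Alignment engine

A single seed-and-extend local aligner backs 16S screening, ANI, and
recruitment, so the pipeline has no external search dependency.

* **Seeding.** Exact k-mer seeds on both strands via a sorted-array index.
  Seed length is stage-tuned: 12 for 16S work (must find 80 %-identity
  alignments), 16 for ANI fragments, 20 for recruitment (>95 % identity
  only).  Positions per k-mer are capped at 64 to bound low-complexity
  blow-ups.
* **Extension.** X-drop (20) un-gapped extension along each seeded
  diagonal, then a banded (±16 diagonals) affine-gap local refinement —
  but only for alignments that are partial (<90 % of the query; un-gapped
  trimming of mismatched ends is also what full Smith–Waterman would do)
  and near-best (within 10 of the best un-gapped score, the classic
  two-phase HSP strategy).  The refinement runs in a ±128 bp window around
  the un-gapped alignment so chance seeds stay cheap.
* **Scoring.** +1/−2, gap of length g costs 5 + 2g.  Significance is
  Karlin–Altschul: E = K·m·n·exp(−λ·score) with n the total subject
  length (database-size correction, matching search-tool convention).
  λ is the positive root of Σ pᵢpⱼ·exp(λ·s(i,j)) = 1, found by bisection
  (≈1.333 for the default scheme and uniform base frequencies); K is fixed
  at 0.621 — solving for K exactly is analytically awkward and the
  standard nucleotide value is adequate for thresholding at 1e-5.
* **Determinism.** Hits sort by score descending, ties by
  (subject id, subject start); best-hit-per-query applies the same order,
  so every read is counted at most once and identically across runs.
* **Bulk prescreen.** Recruiting 10⁷ reads cannot afford a per-read Python
  search, so read sets are first screened in vectorised chunks: k-mers at
  stride 10 along the forward read are looked up in the union of both
  subject strands' k-mers.  A read with no shared 20-mer cannot pass the
  >95 %/≥50 bp filters; at 2 % read error the chance that all strided
  seeds are disrupted is ~5×10⁻⁵, and zero for error-free reads.

The test suite checks the heuristic against an exhaustive affine
Smith–Waterman oracle on mutated pairs ≤200 bp (substitution rate 0–15 %)
and requires ≥95 % exact top-score agreement.  Fully unrelated random
pairs are excluded from that bar: their optimal local alignments are
word-free chance islands no seeded search tool reports.

## 16S screening cascade

1. **Dereplication** (computational convenience, not inference): greedy
   longest-first centroid clustering; a record joins the first centroid it
   matches at ≥90 % identity over ≥80 % of its own length.  The coverage
   clause is our addition — identity alone is meaningless over a 20 bp
   overlap.
2. **Candidacy**: best-hit e-value < 1e-5 (strict) against the centroids.
3. **Verification**: a log-odds position-weight profile is built from the
   reference set (references are placed on the longest reference's
   coordinate frame by their best un-gapped offset; 0.5 pseudocounts).
   Candidates are scored by their best un-gapped placement on either
   strand, and the pass threshold is calibrated so at most 1 % of
   dinucleotide-shuffled candidates (Altschul–Erikson shuffle, preserving
   exact dinucleotide counts) would pass.  This replaces covariance-model
   alignment: what matters downstream is true/false 16S discrimination,
   which the calibrated profile provides at desk scale.
4. **Classification** against the full, non-dereplicated reference set:
   best hit's taxon iff identity ≥80 % and alignment length ≥90 bp, else
   discarded.  On ~150 bp reads the alignment length is the local
   alignment's length.

Relative abundance is the share of classified reads per taxon.  Statuses
(`not_candidate`, `candidate_rejected`, `classified`, `discarded`)
partition the input reads exactly.

## Binning

Contigs >10 kb with a strict >60 % gene vote for the target taxon
(unlabelled genes count in the denominator — the rule reads "of the total
genes") are summarised by canonical tetranucleotide frequencies: 4-mers
pooled with their reverse complements into 136 classes, N-containing
windows skipped, counts normalised.  PCA is computed by SVD of the centred
profile matrix; components are covariance eigenvectors ordered by
eigenvalue, with each component's largest-magnitude loading made positive
so signs are reproducible.

The clustering feature vector is [PC1–3, GC, log10(depth + 0.1) per
sample], each dimension z-scored.  The log transform reflects that
coverage spans orders of magnitude; the 0.1 pseudocount handles absent
genomes.  Partitioning is PAM k-medoids (build + swap, deterministic) over
Euclidean distances for each candidate k, scored by mean silhouette, with
two guards:

* **Parsimony**: the smallest k within 0.05 silhouette of the best wins,
  so a noise-driven split never displaces an equally good simpler
  partition (the third-plus principal components are near-pure noise but
  are z-scored to unit variance, which otherwise lets spurious splits edge
  ahead).
* **Structure floor**: if even the best silhouette is below 0.35 — midway
  through the conventional "weak structure" band, while random splits of a
  single genome's contigs score ~0.2–0.3 and genuine multi-genome inputs
  ≥0.5 — the contigs stay in one bin.

This automated procedure replaces manual bin drawing in PCA space; it is a
stated substitute, chosen to be deterministic, seedable and auditable, not
a reconstruction of anyone's hand curation.

## Genome quality and streamlining

The marker census is deliberately simple: completeness = % of expected
single-copy markers present at least once; contamination = % of surplus
copies.  Full lineage-placement/collocated-set machinery is out of scope —
downstream only consumes the two percentages.  The estimated genome size
contamination-corrects the assembled length and scales by completeness:

    est_size_Mb = length_Mb × (1 − contamination/100) / (completeness/100)

printed at two decimals.  Coding density is the union of coding intervals
over total length (overlaps counted once).  The median intergenic spacer
takes consecutive same-contig genes sorted by start, with overlaps clamped
to spacer 0 — a negative spacer is an overlap, not spacing.  GC excludes N
from numerator and denominator.

## ANI and dereplication

Fragment ANI in the Goris style: the query genome is cut into consecutive
1020 bp fragments (trailing remainder discarded to keep fragment
statistics homogeneous); each fragment's best hit against the subject
genome is retained iff it reaches ≥30 % identity over ≥70 % of the
fragment; ANI is the mean identity of retained hits, and the retained
fraction is reported.  Zero retained fragments leaves ANI undefined
(non-homologous pair) rather than 0.  ANI is computed per ordered pair;
dereplication groups bins by single linkage on max(both directions) >98 %
(strict) — the conservative choice for declaring two bins the same
organism.  Each group's representative is the most complete bin, ties
broken by length then id.  Under the substitution-only generator the stage
recovers 100(1 − μ) within 0.3 for μ ≤ 0.05 and is exact for self-pairs.

## Recruitment and RPKG

A read is recruited iff its best hit passes alignment ≥50 bp, identity
>95 % (strict), e-value ≤1e-5; each read counts once.  RPKG is

    RPKG = reads recruited / (genome kb × metagenome Gbp)

with "gigabyte of metagenome" read as gigabase-pairs of read sequence
(bytes ≈ bases in flat FASTA).  The implied depth is
coverage = RPKG × Gbp × read length / 1000, so 10 RPKG ↔ 1× for 100 bp
reads in a 1 Gbp metagenome — the identity the acceptance run reproduces
end-to-end.  Whether multi-mapping reads should count once or per hit is
under-specified in common practice; one-per-read is the documented choice
here, with ties resolved by the aligner's deterministic order.

## FISH census

Relative density = probe-positive fraction of DAPI objects × DAPI direct
count per mL; percent-of-group = 100 × probe density / group density, with
values >100 % reported with a warning (counting noise) rather than capped.
Filtration-volume and filter-area calibration is assumed folded into the
supplied DAPI counts.

## Orchestration and reproducibility

`limnobin run` wires the stages on a YAML config.  Every stochastic stage
derives its seed as (global seed × 1000003 + CRC32(stage name)) mod 2³¹,
so stages are independent yet reproducible; rerunning a config yields
byte-identical tables.  The 16S and recruitment stages cache their output
tables keyed by a digest of (config, seed) and are skipped on rerun with
the same key; lighter stages recompute.  The manifest records thresholds,
seeds, stage keys, timings and the output inventory.

## Problem sizes

The test and acceptance workloads use: 100–400 kb genomes for binning and
ANI (three 400 kb genomes, ΔGC ≥ 5 %, coverages 2/4/8× for bin recovery;
300 kb pairs for ANI recovery), a 64-reference/8-taxon 16S set with 10⁴
mixed reads for the screening cascade, and a 1 Mbp genome in a 1.0 Gbp
(10⁷-read) metagenome for the RPKG identity.  These sizes were chosen so
each property is measured with comfortable statistical margin on a single
CPU; the estimators themselves are size-agnostic.

## Known limitations

* The aligner is a heuristic: no translated search, no
  composition-adjusted statistics, fixed band, fixed K.
* The marker census ignores marker collocation and lineage-specific
  weighting, so its percentages are not comparable to tools that model
  those.
* The profile-based 16S verifier is position-weight only (no secondary
  structure) and is calibrated per candidate set.
* Binning uses a single automated clustering path; it does not attempt
  paired-read linkage or cross-sample co-assembly refinement.
* The FISH module is pure census arithmetic; probe design and image
  analysis are out of scope.
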