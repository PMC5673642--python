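"""End-to-end orchestration of the synthetic-community analysis.

Stage order: simulate -> 16S screen -> recruitment/coverage -> binning ->
genome QC -> ANI/dereplication -> report bundle.  Every stochastic stage
draws its seed deterministically from the global seed and the stage name,
so reruns with the same config produce byte-identical tables.  Expensive
stage outputs (16S abundance, per-contig recruitment) are cached on disk
keyed by a digest of the config and seed, and reloaded on rerun.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ani as ani_mod
from . import binning, qc, recruitment, ssu
from .io_core import (GeneCall, PipelineThresholds, SequenceRecord, logger,
                      write_gene_calls, write_sequences, write_table)
from .synthetic import (CommunityBundle, CommunityDesign, GenomeSpec,
                        _stage_seed, simulate_community)


@dataclass
class RunManifest:
    config: dict
    thresholds: dict
    seed: int
    stage_keys: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise KeyError(f"config missing required key: {key!r}")
    return cfg[key]


def design_from_config(config: dict, seed: int) -> tuple[CommunityDesign, dict]:
    comm = _require(config, "community")
    genome_cfgs = _require(comm, "genomes")
    samples = comm.get("samples") or [f"S{i+1}" for i in range(len(genome_cfgs[0]["coverage"]))]
    marker_size = int(config.get("marker_set_size", 40))
    marker_ids = [f"M{i+1:03d}" for i in range(marker_size)]
    specs, coverage = [], []
    for gcfg in genome_cfgs:
        n_mark = int(gcfg.get("n_markers", marker_size))
        specs.append(
            GenomeSpec(
                genome_id=gcfg["id"],
                length_bp=int(gcfg["length_bp"]),
                gc_target=float(gcfg["gc"]),
                composition_seed=_stage_seed(seed, f"genome:{gcfg['id']}")
                if gcfg.get("composition_seed") is None else int(gcfg["composition_seed"]),
                taxon=gcfg.get("taxon", config.get("target_taxon", "Verrucomicrobia")),
                n_16s_copies=int(gcfg.get("n_16s_copies", 1)),
                marker_ids_planted=tuple(marker_ids[:n_mark]),
            )
        )
        coverage.append([float(c) for c in gcfg["coverage"]])
    design = CommunityDesign(
        genome_specs=specs,
        coverage=np.array(coverage),
        read_length_bp=int(comm.get("read_length_bp", 100)),
        per_base_error=float(comm.get("per_base_error", 0.005)),
        metagenome_target_gbp=float(comm.get("metagenome_target_gbp", 0.0)),
        seed=_stage_seed(seed, "reads"),
        sample_ids=list(samples),
    )
    return design, {"marker_ids": marker_ids,
                    "contig_min_bp": int(comm.get("contig_min_bp", 10000)),
                    "contig_mean_bp": int(comm.get("contig_mean_bp", 25000))}


def run_pipeline(config: dict, outdir, seed: int | None = None) -> RunManifest:
    """Run the full pipeline on a simulation config; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 42) if seed is None else seed)
    th = PipelineThresholds.from_dict(config.get("thresholds", {}))
    target_taxon = config.get("target_taxon", "Verrucomicrobia")
    manifest = RunManifest(config=config, thresholds=th.as_dict(), seed=seed)
    base_key = _digest({"config": config, "seed": seed})
    cache_file = outdir / "cache_keys.json"
    old_keys = json.loads(cache_file.read_text()) if cache_file.exists() else {}

    def cached(stage: str, path: Path) -> bool:
        key = f"{base_key}:{stage}"
        manifest.stage_keys[stage] = key
        return old_keys.get(stage) == key and path.exists()

    def timed(stage, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest.stage_seconds[stage] = round(time.time() - t0, 2)
        logger.info("stage %s done in %.1fs", stage, manifest.stage_seconds[stage])
        return out

    # --- simulate (always recomputed; cheap and everything depends on it)
    design, extra = design_from_config(config, seed)
    bundle: CommunityBundle = timed(
        "simulate",
        lambda: simulate_community(design, extra["contig_min_bp"], extra["contig_mean_bp"]),
    )
    write_sequences(bundle.contigs, outdir / "contigs.fna")
    write_gene_calls(bundle.truth.gene_calls + bundle.truth.marker_calls,
                     outdir / "genes.gff3")
    write_table(
        [{"contig_id": c, "genome_id": g} for c, g in sorted(bundle.truth.contig_to_genome.items())],
        outdir / "truth_contigs.tsv",
    )

    # --- 16S screening per sample (on the raw reads)
    ssu_path = outdir / "ssu_abundance.tsv"

    def run_ssu():
        if bundle.ref_db is None:
            return None
        cdb = ssu.dereplicate_references(bundle.ref_db, th.derep_identity)
        profile = ssu.SSUProfile.fit(bundle.ref_db.records)
        rows = []
        for sid in design.sample_ids:
            classified = ssu.screen_reads(
                bundle.reads[sid], bundle.ref_db, th,
                seed=_stage_seed(seed, f"ssu:{sid}"), cdb=cdb, profile=profile,
            )
            try:
                abund = ssu.taxon_relative_abundance(classified)
            except ValueError:
                abund = {}
            for taxon, pct in abund.items():
                rows.append({"sample": sid, "taxon": taxon, "percent": pct})
        write_table(rows, ssu_path, thresholds=th)
        return rows

    if not cached("ssu", ssu_path):
        timed("ssu", run_ssu)

    # --- recruitment: per-sample best hits against the contig set
    recruit_path = outdir / "recruitment_per_contig.tsv"

    def run_recruit():
        rows = []
        for sid in design.sample_ids:
            n, hits = recruitment.recruit(bundle.reads[sid], bundle.contigs, th)
            per_contig: dict[str, list] = {}
            for h in hits:
                per_contig.setdefault(h.subject_id, []).append(h)
            for c in bundle.contigs:
                hs = per_contig.get(c.id, [])
                rows.append(
                    {
                        "sample": sid,
                        "contig_id": c.id,
                        "reads_recruited": len(hs),
                        "bases_aligned": sum(h.aln_len for h in hs),
                        "depth": binning.coverage_estimate(len(c), hs),
                    }
                )
        write_table(rows, recruit_path, float_fmt="%.4f", thresholds=th)
        return rows

    if cached("recruit", recruit_path):
        rec_df = pd.read_csv(recruit_path, sep="\t", comment="#")
    else:
        timed("recruit", run_recruit)
        rec_df = pd.read_csv(recruit_path, sep="\t", comment="#")

    coverage = {
        sid: dict(zip(sub["contig_id"], sub["depth"]))
        for sid, sub in rec_df.groupby("sample")
    }

    # --- binning
    features = timed(
        "features",
        lambda: binning.compute_features(
            bundle.contigs, bundle.truth.gene_calls, target_taxon, coverage, th
        ),
    )
    write_table(
        [
            {
                "contig_id": f.contig_id, "gc": f.gc,
                "vote_fraction": f.vote_fraction,
                "passes": f.passes_taxon_filter,
                **{f"depth_{s}": c for s, c in zip(design.sample_ids, f.coverage)},
                **{f"pc{i+1}": v for i, v in enumerate(f.pca_scores[:3])},
            }
            for f in features
        ],
        outdir / "contig_features.tsv", float_fmt="%.4f", thresholds=th,
    )
    bins = timed(
        "bin",
        lambda: binning.cluster_contigs(features, seed=_stage_seed(seed, "bin")),
    )
    write_table(
        [{"contig_id": c, "bin_id": b.bin_id} for b in bins for c in b.contig_ids],
        outdir / "bin_membership.tsv", thresholds=th,
    )

    # --- QC (marker census from truth annotations)
    markers = qc.MarkerSet(tuple(extra["marker_ids"]))
    contig_by_id = {c.id: c for c in bundle.contigs}
    all_genes = bundle.truth.gene_calls + bundle.truth.marker_calls
    mag_rows = []
    for b in bins:
        contigs = [contig_by_id[c] for c in b.contig_ids]
        copies = qc.marker_occurrences(b.contig_ids, bundle.truth.marker_calls, markers)
        mag_rows.append(
            qc.build_mag_record(b.bin_id, contigs, all_genes, copies, markers,
                                origin="synthetic", class_label=target_taxon)
        )
    write_table(mag_rows, outdir / "mag_table.tsv", thresholds=th)

    # --- per-bin RPKG from the cached recruitment counts
    contig_to_bin = {c: b.bin_id for b in bins for c in b.contig_ids}
    rpkg_rows = []
    for b in bins:
        genome_kb = sum(len(contig_by_id[c]) for c in b.contig_ids) / 1e3
        for sid in design.sample_ids:
            sub = rec_df[(rec_df["sample"] == sid)
                         & rec_df["contig_id"].map(lambda c: contig_to_bin.get(c) == b.bin_id)]
            nreads = int(sub["reads_recruited"].sum())
            meta_gb = bundle.reads[sid].total_bases / 1e9
            rpkg_rows.append(
                recruitment.RPKGRecord(b.bin_id, sid, nreads, genome_kb, meta_gb,
                                       recruitment.rpkg(nreads, genome_kb, meta_gb))
            )
    write_table(rpkg_rows, outdir / "rpkg_long.tsv", float_fmt="%.4f", thresholds=th)
    recruitment._records_to_wide(rpkg_rows).to_csv(outdir / "rpkg_matrix.tsv", sep="\t")

    # --- ANI + dereplication between bins
    bin_seqs = {b.bin_id: [contig_by_id[c] for c in b.contig_ids] for b in bins}
    eligible = {
        bid: seqs for bid, seqs in bin_seqs.items()
        if sum(len(s) for s in seqs) >= 2 * th.ani_fragment_bp
    }
    results = timed("ani", lambda: ani_mod.ani_matrix(eligible, th))
    write_table(
        [
            {"genome_a": r.genome_a, "genome_b": r.genome_b,
             "ani": r.ani if r.ani is not None else None,
             "n_fragments_used": r.n_fragments_used,
             "fraction_aligned": r.fraction_aligned}
            for r in results.values()
        ],
        outdir / "ani_pairs.tsv", thresholds=th,
    )
    comp = {m.bin_id: m.completeness for m in mag_rows}
    lens = {m.bin_id: m.length_mb for m in mag_rows}
    groups = ani_mod.dereplicate_bins(
        list(eligible), {k: v for k, v in results.items()},
        th.ani_same_organism, comp, lens,
    )
    write_table(
        [
            {"bin_id": m, "group_id": g.group_id,
             "representative": m == g.representative}
            for g in groups for m in g.members
        ],
        outdir / "derep_groups.tsv", thresholds=th,
    )

    manifest.outputs = sorted(
        p.name for p in outdir.iterdir()
        if p.suffix in (".tsv", ".fna", ".gff3")
    )
    cache_file.write_text(json.dumps(manifest.stage_keys, indent=2, sort_keys=True))
    manifest.write(outdir / "manifest.json")
    return manifest
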