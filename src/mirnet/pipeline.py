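"""End-to-end orchestration on synthetic inputs.

``run_all`` wires every stage in dependency order — simulate, clean,
discover, classify, context, express, target, correlate, network — from a
single :class:`PipelineConfig` whose keys surface every analysis
threshold (cluster gap 10 kb, promoter 2000 nt, expectation <= 3.0,
energy ratio 0.75, <10/>500 RPM classes, k = 16, conservation +/-1 nt and
<= 2 mismatches, degradome categories {0,1,2}, >= 2-method intersection).
Outputs are plain-text files stamped with the config hash and seed; a
rerun with an identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import context, correlation, discovery, expression, io, network
from . import srna, synthio, targeting
from .types import ExpressionMatrix, GenomicInterval, ReadStack


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "mirnet_out"
    # synthetic genome
    n_mirna: int = 30
    n_sirna: int = 30
    genome_length: int = 1_000_000
    # sRNA libraries
    tissues: tuple[str, ...] = ("root", "stem", "leaf", "flower")
    n_reps: int = 2
    library_depth: int = 50_000
    read_precision: float = 0.9
    # discovery
    min_precision: float = 0.75
    min_total_reads: int = 10
    max_duplex_mismatches: int = 5
    max_asymmetric_bulge: int = 3
    flank: int = 250
    max_window: int = 300
    # conservation
    conservation_flank: int = 1
    conservation_mismatches: int = 2
    focal_clade: str = "Asteraceae"
    # genomic context
    cluster_gap: int = 10_000
    cluster_mode: str = "gap"
    min_anchors: int = 5
    max_anchor_gap: int = 25
    # expression
    low_rpm: float = 10.0
    high_rpm: float = 500.0
    kmeans_k: int = 16
    # targeting
    expectation_cutoff: float = 3.0
    hybrid_cutoff: float = 0.75
    retained_categories: tuple[int, ...] = (0, 1, 2)
    use_degradome: bool = True
    consensus_for_mti: str = "intersection"  # or "union"
    n_background_transcripts: int = 30
    degradome_signal: int = 50
    degradome_noise: int = 2_000
    # correlation
    negative_fraction: float = 0.46
    expression_noise_sd: float = 0.05
    r_cut: float = -0.9
    p_cut: float = 0.05
    # network
    promoter_upstream: int = 2000
    tfbs_threshold: float = 0.85
    n_tfs: int = 5
    n_tf_sites: int = 60

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "retained_categories"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunResult:
    config: PipelineConfig
    outputs: dict[str, str] = field(default_factory=dict)
    stats: dict[str, object] = field(default_factory=dict)
    truth: synthio.TruthSet | None = None
    loci: list = field(default_factory=list)


def _merge_stacks(per_lib: dict[str, list[ReadStack]]) -> list[ReadStack]:
    merged: dict[str, ReadStack] = {}
    for lib, stacks in per_lib.items():
        for st in stacks:
            tgt = merged.setdefault(st.sequence, ReadStack(st.sequence, {}))
            tgt.per_library_counts[lib] = \
                tgt.per_library_counts.get(lib, 0) + st.per_library_counts[lib]
    return [merged[s] for s in sorted(merged)]


def run_all(config: PipelineConfig) -> RunResult:
    """Execute every stage; any stage failure aborts with its name."""
    res = RunResult(config)
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    res = _run_stages(config, res)
    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": res.outputs,
        "stats": res.stats,
    }
    path = os.path.join(out, "run_log.json")
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    res.outputs["run_log"] = path
    return res


def _run_stages(cfg: PipelineConfig, res: RunResult) -> RunResult:
    out = cfg.outdir
    p = lambda name: os.path.join(out, name)  # noqa: E731
    stage = "simulate"
    try:
        return _stages_body(cfg, res, p)
    except Exception as exc:  # noqa: BLE001 — abort with stage name and cause
        stage = getattr(exc, "mirnet_stage", stage)
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc


def _stages_body(cfg: PipelineConfig, res: RunResult, p) -> RunResult:
    # --- simulate -------------------------------------------------------
    genome, truth = synthio.generate_genome_with_hairpins(
        cfg.n_mirna, cfg.n_sirna, cfg.genome_length, seed=cfg.seed)
    res.truth = truth
    io.write_fasta(genome, p("genome.fa"))
    res.outputs["genome"] = p("genome.fa")

    per_lib: dict[str, list[ReadStack]] = {}
    samples: dict[str, tuple[str, str]] = {}
    for ti, tissue in enumerate(cfg.tissues):
        for rep in range(cfg.n_reps):
            lib = f"{tissue}.R{rep + 1}"
            samples[lib] = (tissue, f"R{rep + 1}")
            lib_seed = (cfg.seed * 1000 + ti * 10 + rep + 1) % 2**31
            per_lib[lib] = synthio.generate_srna_library(
                truth, genome, depth=cfg.library_depth,
                precision=cfg.read_precision, seed=lib_seed,
                library_id=lib, tissue=tissue)

    # --- clean / collapse ----------------------------------------------
    merged = _merge_stacks(per_lib)
    io.write_collapsed_fasta(merged, p("stacks.fa"))
    res.outputs["stacks"] = p("stacks.fa")
    pred = srna.select_prediction_reads(merged)
    profile = srna.length_profile(merged, "clean")
    io.write_tsv(pd.Series(profile, name="rf").rename_axis("length").to_frame(),
                 p("length_profile.tsv"))

    # --- discover -------------------------------------------------------
    crit = discovery.Criteria(
        min_precision=cfg.min_precision,
        min_total_reads=cfg.min_total_reads,
        max_duplex_mismatches=cfg.max_duplex_mismatches,
        max_asymmetric_bulge=cfg.max_asymmetric_bulge)
    loci, _rej = discovery.discover_loci(
        pred, genome, thresholds=crit, flank=cfg.flank,
        max_window=cfg.max_window)
    res.loci = loci
    res.stats["n_loci"] = len(loci)

    # --- classify -------------------------------------------------------
    catalog = synthio.generate_reference_catalog(
        truth, focal_clade=cfg.focal_clade, seed=cfg.seed)
    cons.classify_all(loci, catalog, flank=cfg.conservation_flank,
                      max_mismatch=cfg.conservation_mismatches)
    io.write_loci_gff(loci, p("loci.gff3"))
    res.outputs["loci"] = p("loci.gff3")
    if loci:
        census = cons.family_census(loci)
        res.stats["conservation"] = census["class_counts"]
        io.write_tsv(pd.Series(census["family_members"], name="members")
                     .rename_axis("family").to_frame(), p("families.tsv"))

    # --- context --------------------------------------------------------
    clusters = context.find_clusters(loci, max_gap=cfg.cluster_gap,
                                     mode=cfg.cluster_mode)
    res.stats["n_clusters"] = len(clusters)
    anchors, _planted_blocks = synthio.generate_anchor_table(seed=cfg.seed)
    blocks = context.detect_blocks(anchors, min_anchors=cfg.min_anchors,
                                   max_anchor_gap=cfg.max_anchor_gap)
    res.stats["n_synteny_blocks"] = len(blocks)
    cluster_rows = [(i + 1, loc.id, loc.precursor.chrom, loc.precursor.start)
                    for i, cl in enumerate(clusters) for loc in cl]
    io.write_tsv(pd.DataFrame(cluster_rows,
                              columns=["cluster", "locus", "chrom", "start"]),
                 p("clusters.tsv"), index=False)

    # --- express --------------------------------------------------------
    totals = {lib: sum(st.total_count for st in stacks)
              for lib, stacks in per_lib.items()}
    # the merged prediction stacks carry both per-library counts and the
    # genomic placements recorded during discovery
    stacks_per_lib = {lib: pred for lib in per_lib}
    rpm, raw = expression.quantify_mirna(stacks_per_lib, loci, totals, samples)
    io.write_tsv(rpm.to_frame(), p("mirna_rpm.tsv"))
    res.outputs["mirna_rpm"] = p("mirna_rpm.tsv")
    if len(loci) >= 2:
        patterns = expression.classify_patterns(rpm, cfg.low_rpm, cfg.high_rpm)
        k = min(cfg.kmeans_k, len(loci))
        clusters_km = expression.cluster_profiles(rpm, k=k, seed=cfg.seed)
        de = expression.differential_expression(
            raw, samples, totals, cfg.tissues[0], cfg.tissues[1])
        io.write_tsv(pd.DataFrame({"pattern": patterns, "cluster": clusters_km}),
                     p("expression_classes.tsv"))
        io.write_tsv(de, p(f"de_{cfg.tissues[0]}_vs_{cfg.tissues[1]}.tsv"))
        res.stats["patterns"] = patterns.value_counts().to_dict()

    # --- target ---------------------------------------------------------
    transcripts, truth = synthio.generate_transcriptome(
        truth, n_background=cfg.n_background_transcripts, seed=cfg.seed)
    io.write_fasta(transcripts, p("transcripts.fa"))
    degradome = None
    if cfg.use_degradome:
        degradome = synthio.generate_degradome_library(
            truth, transcripts, signal_reads=cfg.degradome_signal,
            noise_reads=cfg.degradome_noise, seed=cfg.seed)
        io.write_density_table(degradome, p("degradome.tsv"))
    mirna_seqs = {loc.id: loc.mature_seq for loc in loci}
    evidence = targeting.predict_targets(
        mirna_seqs, transcripts, degradome,
        expectation_cutoff=cfg.expectation_cutoff,
        hybrid_cutoff=cfg.hybrid_cutoff,
        retained_categories=frozenset(cfg.retained_categories))
    union, intersection = targeting.consensus(evidence)
    ev_rows = [(r.mirna_id, r.transcript_id, r.site_start, r.expectation,
                r.energy_ratio, r.degradome_category,
                ",".join(sorted(r.methods))) for r in union]
    io.write_tsv(pd.DataFrame(ev_rows, columns=[
        "mirna", "transcript", "site_start", "expectation", "energy_ratio",
        "category", "methods"]), p("target_evidence.tsv"), index=False)
    res.outputs["targets"] = p("target_evidence.tsv")
    res.stats["n_union"] = len(union)
    res.stats["n_intersection"] = len(intersection)

    # --- correlate ------------------------------------------------------
    mir_expr, tx_expr = synthio.generate_expression_profiles(
        truth, n_tissues=len(cfg.tissues), n_reps=cfg.n_reps,
        negative_fraction=cfg.negative_fraction,
        noise_sd=cfg.expression_noise_sd, seed=cfg.seed)
    pairs = [(pt.mirna_id, pt.transcript_id)
             for pt in truth.planted_target_pairs]
    records = correlation.correlate(mir_expr, tx_expr, pairs)
    io.write_tsv(correlation.records_frame(records),
                 p("correlations.tsv"), index=False)
    res.outputs["correlations"] = p("correlations.tsv")
    frac, hits, total = correlation.negative_fraction(
        records, r_cut=cfg.r_cut, p_cut=cfg.p_cut)
    res.stats["strict_negative_fraction"] = frac
    res.stats["correlation_bins"] = correlation.bin_records(records)

    # --- network --------------------------------------------------------
    id_map = _match_to_planted(loci, truth)
    chosen = intersection if cfg.consensus_for_mti == "intersection" else union
    mti_pairs = sorted({(id_map.get(r.mirna_id, r.mirna_id), r.transcript_id)
                        for r in chosen})
    target_ids = sorted({g for _m, g in mti_pairs})
    mirna_ids = sorted({m for m, _g in mti_pairs})
    prom_features = {loc.id: loc.precursor for loc in loci}
    genomic_promoters, _trunc = network.extract_promoters(
        prom_features, genome, upstream=cfg.promoter_upstream)
    io.write_fasta(genomic_promoters, p("mirna_promoters.fa"))

    pwms, prom_seqs, _sites = synthio.generate_tf_motifs_and_promoters(
        n_tfs=cfg.n_tfs, n_sites=cfg.n_tf_sites,
        n_promoters=max(1, len(mirna_ids) + len(target_ids)),
        seed=cfg.seed)
    renamed = dict(zip(sorted(prom_seqs), mirna_ids + target_ids))
    prom_by_entity = {renamed[k]: v for k, v in prom_seqs.items()
                      if k in renamed}
    io.write_pwms(pwms, p("pwms.txt"))
    mir_proms = {k: v for k, v in prom_by_entity.items() if k in set(mirna_ids)}
    tgt_proms = {k: v for k, v in prom_by_entity.items() if k in set(target_ids)}
    tmi_hits = network.scan_tfbs(mir_proms, pwms, cfg.tfbs_threshold)
    tti_hits = network.scan_tfbs(tgt_proms, pwms, cfg.tfbs_threshold)
    tmi, tti, mti = network.build_tables(tmi_hits, tti_hits, mti_pairs)
    cascades, ffls = network.enumerate_motifs(tmi, mti, tti)
    res.stats.update(n_tmi=len(tmi), n_tti=len(tti), n_mti=len(mti),
                     n_cascades=len(cascades), n_ffls=len(ffls))
    graph = network.build_graph(tmi, mti, tti)
    paths = network.export_network(graph, p("network"))
    res.outputs.update(paths)
    return res


def _match_to_planted(loci, truth: synthio.TruthSet) -> dict[str, str]:
    """Map discovered locus ids to planted locus ids by mature overlap."""
    out = {}
    for loc in loci:
        for pm in truth.planted_mirna_loci:
            if loc.mature.overlaps(pm.mature) and \
                    loc.mature.strand == pm.mature.strand:
                out[loc.id] = pm.locus_id
                break
    return out
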