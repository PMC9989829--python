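"""End-to-end per-species pipeline over a simulated (or ingested) bundle.

Stages: per sample, DNA pileup -> genotypes -> reference adjustment ->
RNA alignment (internal ungapped aligner) -> standard site calling ->
hyper-editing detection on the alignment rejects -> per-sample merge;
then species-level recovery and filters, followed by the landscape,
antisense, motif and recoding characterizations.  All thresholds default
to the published calling parameters and live in one config block.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import _seq, antisense as antisense_mod, io, landscape as landscape_mod
from . import merge as merge_mod, motif as motif_mod, recoding as recoding_mod
from .align import UngappedAligner
from .hyper import HyperCandidatePair, run_hyper_stage
from .pileup import Pileup, build_pileup
from .sitecall import adjust_reference, call_candidate_sites, call_genotypes
from .types import AlignedRead, GenomeSeq


@dataclass
class PipelineConfig:
    """All tunable thresholds, defaulting to the published calling values."""

    # pileup / alignment floors
    dna_min_mapq: int = 5
    rna_min_mapq: int = 20
    dna_min_baseq: int = 30
    rna_min_baseq: int = 30
    read2_sense: bool = True  # dUTP chemistry; False for the opposite protocol
    aligner_k: int = 13
    max_mismatches: int = 4  # standard-pass mismatch tolerance per mate
    hyper_max_mismatches: int = 6  # transformed-space tolerance

    # genotyping / calling
    genotype_min_depth: int = 10
    genotype_hom_fraction: float = 0.95
    standard_min_support: int = 3
    standard_min_level: float = 0.05
    hyper_min_support: int = 2

    # recovery and species filters
    error_p: float = 0.001
    recovery_fdr: float = 0.01
    dna_variant_max_freq: float = 0.1

    # landscape / antisense / recoding windows
    cluster_max_gap: int = 30
    cluster_min_size: int = 3
    control_depth_tolerance: float = 0.2
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SampleResult:
    sample_id: str
    adjusted_genome: GenomeSeq
    dna_pileup: Pileup
    rna_pileup: Pileup
    genotypes: object
    standard_sites: list
    hyper_sites: list
    merged_sites: list
    n_rna_pairs: int = 0
    n_harvested: int = 0
    adjust_changes: int = 0
    hyper_summary: object = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: GenomeSeq
    repeats: list
    genes: list
    samples: dict[str, SampleResult]
    editome: merge_mod.SpeciesEditome
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _iter_fastq_pairs(r1_path: str, r2_path: str):
    for (n1, s1, q1), (n2, s2, q2) in zip(
        io.read_fastq(r1_path), io.read_fastq(r2_path)
    ):
        if n1 != n2:
            raise ValueError(f"unpaired FASTQ records: {n1} vs {n2}")
        yield n1, _seq.encode(s1), q1, _seq.encode(s2), q2


def align_rna_sample(
    r1_path: str,
    r2_path: str,
    genome: GenomeSeq,
    cfg: PipelineConfig,
) -> tuple[list[tuple[AlignedRead, AlignedRead]], list[HyperCandidatePair], int]:
    """Align a sample's RNA pairs; return (aligned pairs, harvested, n_pairs).

    Pairs that fail to align concordantly, or whose placement is ambiguous
    (MAPQ < 20), are harvested for the hyper-editing stage.
    """
    aligner = UngappedAligner(genome, k=cfg.aligner_k)
    aligned, harvested = [], []
    n = 0
    for rid, c1, q1, c2, q2 in _iter_fastq_pairs(r1_path, r2_path):
        n += 1
        hit = aligner.align_pair(c1, c2, max_mm=cfg.max_mismatches)
        if hit is None or hit.mapq1 < cfg.rna_min_mapq or hit.mapq2 < cfg.rna_min_mapq:
            harvested.append(
                HyperCandidatePair(
                    rid, c1, q1, c2, q2,
                    "unaligned" if hit is None else "mapq_lt_20",
                )
            )
            continue
        reads = []
        for mate, codes, quals, h in ((1, c1, q1, hit.hit1), (2, c2, q2, hit.hit2)):
            if h.strand == "-":
                codes, quals = _seq.revcomp_codes(codes), quals[::-1]
            reads.append(
                AlignedRead(rid, mate, h.chrom, h.start, h.strand, 37, codes, quals)
            )
        aligned.append((reads[0], reads[1]))
    return aligned, harvested, n


def process_sample(
    bundle_dir: str,
    sid: str,
    genome: GenomeSeq,
    cfg: PipelineConfig,
) -> SampleResult:
    dna_reads = io.read_sam(os.path.join(bundle_dir, f"{sid}.dna.truth.sam"))
    dna_pile = build_pileup(
        dna_reads, genome, min_baseq=cfg.dna_min_baseq,
        min_mapq=cfg.dna_min_mapq, stranded=False,
    )
    genotypes = call_genotypes(
        dna_pile, cfg.genotype_min_depth, cfg.genotype_hom_fraction
    )
    adjusted, changes = adjust_reference(genome, genotypes)
    aligned, harvested, n_pairs = align_rna_sample(
        os.path.join(bundle_dir, f"{sid}.rna.R1.fastq"),
        os.path.join(bundle_dir, f"{sid}.rna.R2.fastq"),
        adjusted, cfg,
    )
    rna_pile = build_pileup(
        (r for pair in aligned for r in pair),
        adjusted, min_baseq=cfg.rna_min_baseq, min_mapq=cfg.rna_min_mapq,
        stranded=True, read2_sense=cfg.read2_sense,
    )
    standard = call_candidate_sites(
        rna_pile, genotypes, sid,
        min_support=cfg.standard_min_support, min_level=cfg.standard_min_level,
    )
    hyper_sites, hyper_summary = run_hyper_stage(
        harvested, adjusted, genotypes, sid,
        max_mm=cfg.hyper_max_mismatches, read2_sense=cfg.read2_sense,
    )
    merged, _dropped = merge_mod.merge_sample_calls(standard, hyper_sites)
    return SampleResult(
        sample_id=sid,
        adjusted_genome=adjusted,
        dna_pileup=dna_pile,
        rna_pileup=rna_pile,
        genotypes=genotypes,
        standard_sites=standard,
        hyper_sites=hyper_sites,
        merged_sites=merged,
        n_rna_pairs=n_pairs,
        n_harvested=len(harvested),
        adjust_changes=len(changes),
        hyper_summary=hyper_summary,
    )


def pooled_rna_pileup(samples: dict[str, SampleResult], genome: GenomeSeq) -> Pileup:
    pile = Pileup(genome, stranded=True, min_baseq=30)
    for sr in samples.values():
        for chrom, arr in sr.rna_pileup.counts.items():
            pile.counts[chrom] += arr
    return pile


def run_pipeline(
    bundle_dir: str, out_dir: str, cfg: PipelineConfig | None = None
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    io.ensure_dir(out_dir)
    genome = io.read_genome(os.path.join(bundle_dir, "genome.fa"))
    repeats = io.read_repeats_bed(os.path.join(bundle_dir, "repeats.bed"))
    genes = io.read_genes_gff3(os.path.join(bundle_dir, "genes.gff3"))
    sample_ids = sorted(
        os.path.basename(p).split(".")[0]
        for p in glob.glob(os.path.join(bundle_dir, "*.rna.R1.fastq"))
    )
    if len(sample_ids) < 2:
        raise ValueError("species-level stages require >= 2 samples")

    samples = {sid: process_sample(bundle_dir, sid, genome, cfg) for sid in sample_ids}

    editome = merge_mod.build_editome({s: r.merged_sites for s, r in samples.items()})
    editome = merge_mod.recover_missed_sites(
        editome,
        {s: r.rna_pileup for s, r in samples.items()},
        {s: r.dna_pileup for s, r in samples.items()},
        error_p=cfg.error_p, fdr=cfg.recovery_fdr,
    )
    editome = merge_mod.dna_variant_filter(
        editome, {s: r.dna_pileup for s, r in samples.items()},
        max_freq=cfg.dna_variant_max_freq,
    )
    editome = merge_mod.cross_sample_conflict_filter(editome)

    result = PipelineResult(cfg, genome, repeats, genes, samples, editome)
    ctx_genome = samples[sample_ids[0]].adjusted_genome  # sequence context source
    sites = editome.sites
    tables = result.tables

    # landscape ---------------------------------------------------------
    masks = landscape_mod.element_masks(ctx_genome, repeats, genes)
    tables["sites_annotated"] = landscape_mod.annotate_sites(sites, masks)
    clustered_rows = []
    for sid, sr in samples.items():
        sdf = editome.df[editome.df["sample"] == sid]
        pos_by_chrom = {
            c: g["pos"].values for c, g in sdf.groupby("chrom")
        }
        clusters, frac = landscape_mod.find_clusters(
            pos_by_chrom, cfg.cluster_max_gap, cfg.cluster_min_size
        )
        ctrl = landscape_mod.sample_control_sites(
            sdf, sr.rna_pileup, ctx_genome,
            seed=cfg.seed + sum(ord(c) for c in sid),
            depth_tolerance=cfg.control_depth_tolerance,
        )
        ctrl_by_chrom = {
            c: g["pos"].values for c, g in ctrl.groupby("chrom")
        } if not ctrl.empty else {}
        _, ctrl_frac = landscape_mod.find_clusters(
            ctrl_by_chrom, cfg.cluster_max_gap, cfg.cluster_min_size
        )
        clustered_rows.append((sid, len(clusters), frac, ctrl_frac))
    tables["clusters"] = pd.DataFrame(
        clustered_rows,
        columns=["sample", "n_clusters", "clustered_fraction", "control_clustered_fraction"],
    )

    classes = list(landscape_mod.GENE_CLASSES) + sorted(
        {r.repeat_class for r in repeats}
    )
    edit_rows = []
    for sid, sr in samples.items():
        sdf = editome.df[editome.df["sample"] == sid]
        for weighted in (False, True):
            e = landscape_mod.editability(
                sdf, sr.rna_pileup, ctx_genome, masks, classes, weighted=weighted
            )
            e.insert(0, "sample", sid)
            e.insert(1, "weighted", weighted)
            edit_rows.append(e)
    tables["editability"] = pd.concat(edit_rows, ignore_index=True)

    div_rows = []
    for sid, sr in samples.items():
        sdf = editome.df[editome.df["sample"] == sid]
        try:
            d = landscape_mod.divergence_bins(sdf, repeats, sr.rna_pileup, ctx_genome)
        except ValueError:
            continue
        d.insert(0, "sample", sid)
        div_rows.append(d)
    if div_rows:
        tables["divergence_bins"] = pd.concat(div_rows, ignore_index=True)

    # antisense ---------------------------------------------------------
    verdicts = antisense_mod.classify_sites(
        sites,
        {s: r.rna_pileup for s, r in samples.items()},
        {s: r.dna_pileup for s, r in samples.items()},
        ctx_genome, repeats,
    )
    tables["antisense_verdicts"] = antisense_mod.verdicts_to_frame(verdicts)
    tables["antisense_pairs"] = antisense_mod.summarize_pairs(verdicts, genes)

    # motif -------------------------------------------------------------
    pooled = pooled_rna_pileup(samples, ctx_genome)
    ai_sites = sites[sites["type"] == "A-to-G"]
    profile = motif_mod.build_motif_profile(ai_sites, pooled, ctx_genome)
    tables["motif_tests"] = motif_mod.position_tests(profile)
    tables["motif_vector"] = pd.DataFrame(
        [motif_mod.preference_vector(profile)],
        columns=[f"{p:+d}{b}" for p, b in motif_mod.VECTOR_ORDER],
    )

    # recoding ----------------------------------------------------------
    candidates = recoding_mod.map_sites_to_codons(sites, genes, ctx_genome)
    retained = recoding_mod.filter_recoding(candidates, editome)
    tables["recoding_candidates"] = recoding_mod.recoding_to_frame(candidates)
    tables["recoding_sites"] = recoding_mod.recoding_to_frame(retained)

    # outputs -----------------------------------------------------------
    tables["editome"] = editome.to_wide()
    prov = editome.df["provenance"].value_counts().to_dict()
    result.summary = {
        "samples": {
            sid: {
                "rna_pairs": sr.n_rna_pairs,
                "harvested_pairs": sr.n_harvested,
                "reference_adjustments": sr.adjust_changes,
                "standard_sites": len(sr.standard_sites),
                "hyper_sites": len(sr.hyper_sites),
                "merged_sites": len(sr.merged_sites),
            }
            for sid, sr in samples.items()
        },
        "editome_positions": int(len(sites)),
        "observations_by_provenance": {k: int(v) for k, v in sorted(prov.items())},
        "clustered_fraction_mean": float(tables["clusters"]["clustered_fraction"].mean()),
        "antisense_candidates": int(tables["antisense_verdicts"]["candidate"].sum()),
        "antisense_pairs": int(len(tables["antisense_pairs"])),
        "recoding_sites": int(len(tables["recoding_sites"])),
    }
    for name, df in tables.items():
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
    filter_log = pd.DataFrame(editome.filter_log)
    filter_log.to_csv(os.path.join(out_dir, "filter_log.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


# ------------------------------------------------------------------ truth eval


def evaluate_against_truth(result: PipelineResult, bundle_dir: str) -> dict:
    """Confusion statistics of the pipeline output against planted truth."""
    truth = pd.read_csv(os.path.join(bundle_dir, "truth_sites.tsv"), sep="\t")
    snps = pd.read_csv(os.path.join(bundle_dir, "truth_snps.tsv"), sep="\t")
    truth["pos"] = truth["pos_1based"] - 1
    snps["pos"] = snps["pos_1based"] - 1
    sites = result.editome.sites
    final_pos = set(zip(sites["chrom"], sites["pos"], sites["strand"]))

    # standard-pass sensitivity on isolated sites at RNA depth >= 10
    iso = truth[truth["category"] == "isolated"]
    n_eval = n_hit = 0
    for sid, sr in result.samples.items():
        std = {(s.chrom, s.pos, s.strand) for s in sr.standard_sites}
        for r in iso.itertuples(index=False):
            depth = int(sr.rna_pileup.depth(r.chrom, r.strand)[r.pos])
            if depth >= 10:
                n_eval += 1
                n_hit += (r.chrom, r.pos, r.strand) in std
    standard_sensitivity = n_hit / n_eval if n_eval else np.nan

    snp_pos = set(zip(snps["chrom"], snps["pos"]))
    fp_at_snps = sum(1 for c, p, _ in final_pos if (c, p) in snp_pos)

    members = truth[truth["category"] == "cluster"]
    hyper_union = {
        (s.chrom, s.pos, s.strand)
        for sr in result.samples.values()
        for s in sr.hyper_sites
    }
    hyper_recall = (
        sum(
            1
            for r in members.itertuples(index=False)
            if (r.chrom, r.pos, r.strand) in hyper_union
        )
        / len(members)
        if len(members)
        else np.nan
    )

    atog = float((sites["type"] == "A-to-G").mean()) if len(sites) else np.nan

    truth_all = set(zip(truth["chrom"], truth["pos"], truth["strand"]))
    recall_all = (
        sum(1 for k in truth_all if k in final_pos) / len(truth_all)
        if truth_all
        else np.nan
    )
    anti = truth[truth["category"] == "antisense"]
    anti_keys = set(zip(anti["chrom"], anti["pos"], anti["strand"]))
    anti_recall = (
        sum(1 for k in anti_keys if k in final_pos) / len(anti_keys)
        if anti_keys
        else np.nan
    )
    return {
        "standard_sensitivity": standard_sensitivity,
        "standard_sensitivity_n": n_eval,
        "final_sites_at_snp_positions": fp_at_snps,
        "hyper_member_recall": hyper_recall,
        "hyper_member_n": int(len(members)),
        "a_to_g_fraction": atog,
        "overall_recall": recall_all,
        "antisense_site_recall": anti_recall,
        "final_positions": len(final_pos),
    }
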