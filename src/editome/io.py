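"""Standard-format I/O: FASTA, FASTQ, SAM, BED repeats, GFF3 genes, TSV tables.

Internal coordinates are 0-based half-open; every emitted table uses
1-based inclusive positions, converted here at the boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from .types import (
    AlignedRead,
    EditingSite,
    GeneModel,
    GenomeSeq,
    Interval,
    RepeatLocus,
)

SITE_TABLE_COLUMNS = [
    "chrom",
    "pos_1based",
    "strand",
    "ref",
    "edited",
    "type",
    "dna_depth",
    "rna_edited",
    "rna_total",
    "level",
    "sample",
    "provenance",
]


# ---------------------------------------------------------------- FASTA


def read_genome(path: str) -> GenomeSeq:
    """Load a FASTA genome; lowercase is uppercased, non-ACGTN becomes N."""
    seqs: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        s = str(rec.seq)
        if not s:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        seqs[rec.id] = _seq.encode(s)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSeq(seqs)


def write_genome(genome: GenomeSeq, path: str) -> None:
    recs = [
        SeqRecord(Seq(genome.string(c)), id=c, description="")
        for c in genome
    ]
    SeqIO.write(recs, path, "fasta")


# ---------------------------------------------------------------- FASTQ


def write_fastq(reads: Iterable[tuple[str, str, np.ndarray]], path: str) -> None:
    """Write (name, sequence, phred-quality-array) records."""
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            q = "".join(chr(int(v) + 33) for v in quals)
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")


def read_fastq(path: str) -> Iterable[tuple[str, str, np.ndarray]]:
    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq), np.asarray(
            rec.letter_annotations["phred_quality"], dtype=np.int16
        )


# ---------------------------------------------------------------- SAM


def _sam_header(genome: GenomeSeq) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome],
    }


def write_sam(
    pairs: Iterable[tuple[AlignedRead, AlignedRead]],
    genome: GenomeSeq,
    path: str,
) -> None:
    """Write ungapped read pairs as a text SAM file (simple nM CIGARs)."""
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome))
    tid = {c: i for i, c in enumerate(genome)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r1, r2 in pairs:
            for rd, mate_rd in ((r1, r2), (r2, r1)):
                a = pysam.AlignedSegment(header)
                a.query_name = rd.read_id
                flag = 0x1 | 0x2
                flag |= 0x40 if rd.mate == 1 else 0x80
                if rd.strand == "-":
                    flag |= 0x10
                if mate_rd.strand == "-":
                    flag |= 0x20
                a.flag = flag
                a.reference_id = tid[rd.chrom]
                a.reference_start = rd.start
                a.mapping_quality = rd.mapq
                a.cigarstring = f"{len(rd.codes)}M"
                a.query_sequence = _seq.decode(rd.codes)
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(int(v) + 33) for v in rd.quals)
                )
                a.next_reference_id = tid[mate_rd.chrom]
                a.next_reference_start = mate_rd.start
                fh.write(a)


def read_sam(path: str) -> Iterable[AlignedRead]:
    """Stream ungapped aligned reads from a SAM file."""
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            cig = a.cigartuples
            if cig is None or len(cig) != 1 or cig[0][0] != 0:
                continue  # only ungapped records are modeled
            quals = (
                np.asarray(a.query_qualities, dtype=np.int16)
                if a.query_qualities is not None
                else np.full(len(a.query_sequence), 40, dtype=np.int16)
            )
            yield AlignedRead(
                read_id=a.query_name,
                mate=2 if a.is_read2 else 1,
                chrom=a.reference_name,
                start=a.reference_start,
                strand="-" if a.is_reverse else "+",
                mapq=a.mapping_quality,
                codes=_seq.encode(a.query_sequence),
                quals=quals,
            )


# ---------------------------------------------------------------- BED / GFF3


def write_repeats_bed(repeats: Sequence[RepeatLocus], path: str) -> None:
    """BED6: name = repeat class, score = divergence x 1000."""
    with open(path, "w") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_class}\t"
                f"{int(round(r.divergence * 1000))}\t{iv.strand}\n"
            )


def read_repeats_bed(path: str) -> list[RepeatLocus]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                RepeatLocus(
                    Interval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "."),
                    f[3],
                    int(f[4]) / 1000.0,
                )
            )
    return out


def write_genes_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            sp = g.span
            fh.write(
                f"{g.chrom}\tsim\tgene\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            feats = (
                [("exon", iv) for iv in g.exons]
                + [("CDS", iv) for iv in g.cds]
                + [("five_prime_UTR", iv) for iv in g.utr5]
                + [("three_prime_UTR", iv) for iv in g.utr3]
            )
            for kind, iv in feats:
                fh.write(
                    f"{g.chrom}\tsim\t{kind}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene_id}.t1\n"
                )


def read_genes_gff3(path: str) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, kind, start, end, _, strand, _, attrs = f[:9]
            att = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            iv = Interval(chrom, int(start) - 1, int(end), strand)
            if kind == "gene":
                genes[att["ID"]] = GeneModel(att["ID"], chrom, strand)
            elif kind == "mRNA":
                mrna_to_gene[att["ID"]] = att["Parent"]
            else:
                gid = mrna_to_gene.get(att["Parent"], att["Parent"])
                g = genes[gid]
                if kind == "exon":
                    g.exons.append(iv)
                elif kind == "CDS":
                    g.cds.append(iv)
                elif kind == "five_prime_UTR":
                    g.utr5.append(iv)
                elif kind == "three_prime_UTR":
                    g.utr3.append(iv)
    out = []
    for g in genes.values():
        for lst in (g.exons, g.cds, g.utr5, g.utr3):
            lst.sort(key=lambda iv: iv.start)
        g.introns = [
            Interval(g.chrom, a.end, b.start, g.strand)
            for a, b in zip(g.exons, g.exons[1:])
            if a.end < b.start
        ]
        out.append(g)
    out.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return out


# ---------------------------------------------------------------- site tables


def sites_to_frame(sites: Iterable[EditingSite]) -> pd.DataFrame:
    rows = [
        (
            s.chrom,
            s.pos + 1,
            s.strand,
            s.ref_base,
            s.edited_base,
            s.subst_type,
            s.dna_depth,
            s.rna_edited,
            s.rna_total,
            round(s.editing_level, 6),
            s.sample_id,
            s.provenance,
        )
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)
    return df.sort_values(
        ["chrom", "pos_1based", "strand", "sample"], kind="mergesort"
    ).reset_index(drop=True)


def write_site_table(sites: Iterable[EditingSite], path: str) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_site_table(path: str) -> list[EditingSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(
            EditingSite(
                chrom=r.chrom,
                pos=int(r.pos_1based) - 1,
                strand=r.strand,
                ref_base=r.ref,
                edited_base=r.edited,
                dna_depth=int(r.dna_depth),
                rna_edited=int(r.rna_edited),
                rna_total=int(r.rna_total),
                sample_id=str(r.sample),
                provenance=r.provenance,
            )
        )
    return out


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
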