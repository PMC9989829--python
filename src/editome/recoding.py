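"""Recoding editing: nonsynonymous A-to-I sites in CDS and their filtering.

Candidates are A-to-I sites on a gene's coding strand within CDS whose
A>G change alters the encoded amino acid.  The putatively beneficial
set applies three filters: (1) hyper-editing-region exclusion — the
candidate lies in a run of more than ten same-type sites with adjacent
gaps <= 20 nt; (2) mixed-type-window exclusion — any other substitution
type within the 25-nt window (+/- 12 nt); (3) recurrence — present in
>= 2 samples with summed RNA depth >= 10 and mean editing level >= 0.1.
The filters are independent predicates, so their order is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .merge import SpeciesEditome
from .stats import fdr_adjust, fisher_exact_2x2
from .types import GeneModel, GenomeSeq


@dataclass
class RecodingSite:
    chrom: str
    pos: int
    strand: str
    gene_id: str
    codon_index: int  # 0-based codon number
    codon_position: int  # 1..3
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    nonsynonymous: bool
    n_samples: int = 0
    sum_depth: int = 0
    mean_level: float = 0.0


def map_sites_to_codons(
    sites: pd.DataFrame, genes: list[GeneModel], genome: GenomeSeq
) -> list[RecodingSite]:
    """Translate every CDS-located A-to-I site into its codon effect.

    Sites whose strand does not match the gene's coding strand are not
    recoding (the edited base is not on the mRNA).  Synonymous sites are
    returned flagged; callers filter on ``nonsynonymous``.  Genes whose
    CDS length is not a multiple of 3 are skipped.
    """
    out = []
    ai = sites[sites["type"] == "A-to-G"]
    for g in genes:
        if g.cds_length() % 3 != 0:
            continue
        coding = g.coding_sequence(genome[g.chrom])
        for r in ai.itertuples(index=False):
            if r.chrom != g.chrom or r.strand != g.strand:
                continue
            c = g.genome_to_coding(r.pos)
            if c is None:
                continue
            ci, cp = divmod(c, 3)
            codon = coding[3 * ci : 3 * ci + 3]
            if codon[cp] != "A":
                continue  # reference disagreement; not an A on the coding strand
            edited = codon[:cp] + "G" + codon[cp + 1 :]
            aa0 = str(Seq(codon).translate())
            aa1 = str(Seq(edited).translate())
            out.append(
                RecodingSite(
                    chrom=r.chrom, pos=r.pos, strand=r.strand, gene_id=g.gene_id,
                    codon_index=ci, codon_position=cp + 1,
                    ref_codon=codon, edited_codon=edited,
                    ref_aa=aa0, edited_aa=aa1, nonsynonymous=aa0 != aa1,
                )
            )
    out.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return out


# ------------------------------------------------------------------ filters


def in_hyper_region(
    chrom: str, pos: int, subst: str, editome_sites: pd.DataFrame,
    max_gap: int = 20, max_sites: int = 10,
) -> bool:
    """True iff the site sits in a same-type run of more than ``max_sites``."""
    same = editome_sites[
        (editome_sites["chrom"] == chrom) & (editome_sites["type"] == subst)
    ]
    p = np.sort(same["pos"].unique())
    if len(p) == 0:
        return False
    i = np.searchsorted(p, pos)
    if i >= len(p) or p[i] != pos:
        return False
    breaks = np.flatnonzero(np.diff(p) > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(p)]])
    for s, e in zip(starts, ends):
        if s <= i < e:
            return e - s > max_sites
    return False


def has_other_type_nearby(
    chrom: str, pos: int, subst: str, editome_sites: pd.DataFrame, window_half: int = 12
) -> bool:
    sub = editome_sites[
        (editome_sites["chrom"] == chrom)
        & (editome_sites["pos"] >= pos - window_half)
        & (editome_sites["pos"] <= pos + window_half)
        & (editome_sites["type"] != subst)
    ]
    return len(sub) > 0


def recurrence_stats(
    chrom: str, pos: int, strand: str, editome: SpeciesEditome
) -> tuple[int, int, float]:
    sub = editome.df[
        (editome.df["chrom"] == chrom)
        & (editome.df["pos"] == pos)
        & (editome.df["strand"] == strand)
    ]
    if sub.empty:
        return 0, 0, 0.0
    return (
        int(sub["sample"].nunique()),
        int(sub["rna_total"].sum()),
        float(sub["level"].mean()),
    )


def filter_recoding(
    candidates: list[RecodingSite],
    editome: SpeciesEditome,
    min_samples: int = 2,
    min_sum_depth: int = 10,
    min_mean_level: float = 0.1,
) -> list[RecodingSite]:
    """Apply the three-filter cascade to nonsynonymous candidates."""
    sites = editome.sites
    kept = []
    for c in candidates:
        if not c.nonsynonymous:
            continue
        if in_hyper_region(c.chrom, c.pos, "A-to-G", sites):
            continue
        if has_other_type_nearby(c.chrom, c.pos, "A-to-G", sites):
            continue
        n, depth, level = recurrence_stats(c.chrom, c.pos, c.strand, editome)
        if n >= min_samples and depth >= min_sum_depth and level >= min_mean_level:
            c.n_samples, c.sum_depth, c.mean_level = n, depth, level
            kept.append(c)
    return kept


def recoding_to_frame(sites: list[RecodingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.chrom, s.pos + 1, s.strand, s.gene_id, s.codon_index + 1,
             s.codon_position, s.ref_codon, s.edited_codon, s.ref_aa, s.edited_aa,
             s.nonsynonymous, s.n_samples, s.sum_depth, round(s.mean_level, 4))
            for s in sites
        ],
        columns=["chrom", "pos_1based", "strand", "gene_id", "codon_number",
                 "codon_position", "ref_codon", "edited_codon", "ref_aa",
                 "edited_aa", "nonsynonymous", "n_samples", "sum_depth",
                 "mean_level"],
    )


# ------------------------------------------------------------------ shared events


@dataclass(frozen=True)
class SharedRecodingEvent:
    column: int  # 0-based alignment column
    aa_from: str
    aa_to: str
    species: tuple[str, ...]
    genes: tuple[str, ...]


def _ungapped_to_column(aligned: str) -> dict[int, int]:
    out = {}
    u = 0
    for col, ch in enumerate(aligned):
        if ch != "-":
            out[u] = col
            u += 1
    return out


def shared_events(
    per_species: dict[str, list[RecodingSite]],
    msa: dict[str, str],
    sibling_pair: tuple[str, str] | None = None,
    min_mean_level: float = 0.1,
    min_samples: int = 2,
) -> list[SharedRecodingEvent]:
    """Recoding events at the same alignment column with the same AA change.

    ``msa`` maps "species|gene_id" to its aligned (gapped) protein
    sequence.  Sites are eligible when their mean level is >= 0.1 or
    they are shared by >= 2 samples.  Events present only in the
    designated sibling species pair are removed.
    """
    by_key: dict[tuple[int, str, str], list[tuple[str, str]]] = {}
    for sp, sites in per_species.items():
        for s in sites:
            if not (s.mean_level >= min_mean_level or s.n_samples >= min_samples):
                continue
            rec = msa.get(f"{sp}|{s.gene_id}")
            if rec is None:
                continue  # recoded protein absent from the alignment
            u2c = _ungapped_to_column(rec)
            col = u2c.get(s.codon_index)
            if col is None:
                continue
            by_key.setdefault((col, s.ref_aa, s.edited_aa), []).append((sp, s.gene_id))
    out = []
    for (col, a0, a1), members in sorted(by_key.items()):
        species = tuple(sorted({sp for sp, _ in members}))
        if len(species) < 2:
            continue
        if sibling_pair is not None and set(species) == set(sibling_pair):
            continue
        out.append(
            SharedRecodingEvent(col, a0, a1, species, tuple(g for _, g in sorted(members)))
        )
    return out


# ------------------------------------------------------------------ enrichment


def go_enrichment(
    recoded_genes: set[str],
    background_genes: set[str],
    gene_terms: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher enrichment of recoded genes per term, BH-corrected.

    The background excludes the recoded genes.  Terms with no annotated
    genes among either set are skipped.
    """
    background = background_genes - recoded_genes
    terms = sorted({t for g in recoded_genes | background for t in gene_terms.get(g, ())})
    rows = []
    for t in terms:
        a = sum(1 for g in recoded_genes if t in gene_terms.get(g, ()))
        b = len(recoded_genes) - a
        c = sum(1 for g in background if t in gene_terms.get(g, ()))
        d = len(background) - c
        if a + c == 0:
            continue
        rows.append((t, a, b, c, d, fisher_exact_2x2(a, b, c, d)))
    df = pd.DataFrame(
        rows, columns=["term", "recoded_in", "recoded_out",
                       "background_in", "background_out", "p_value"]
    )
    if not df.empty:
        df["q_value"] = fdr_adjust(df["p_value"].values)
        df["significant"] = df["q_value"] < fdr
    return df


def rpkm(
    gene: GeneModel, rna_pileups: dict[str, "object"], total_reads: dict[str, float],
    read_length: int = 100,
) -> dict[str, float]:
    """Per-sample RPKM over a gene's exonic span, from stranded pileups."""
    out = {}
    exon_len = sum(len(iv) for iv in gene.exons)
    for sid, pile in rna_pileups.items():
        bases = 0
        for iv in gene.exons:
            bases += int(pile.depth(iv.chrom, gene.strand)[iv.start : iv.end].sum())
        reads = bases / read_length
        out[sid] = reads / (exon_len / 1e3) / (total_reads[sid] / 1e6) if total_reads[sid] else 0.0
    return out
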