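"""Editing from intermolecular sense-antisense dsRNA.

A site is a sense-antisense candidate when (i) a 101-nt window centered
on it is transcribed (depth >= 2 along > 50% of the window) on *both*
strands, (ii) the 51-nt window holds at least one A-to-I site on the
opposite strand, and none of the exclusions fires: a reverse-complement
self-alignment of the 401-nt query within its 4001-nt window (identity
>= 80%, length >= 20, spanning the site — intramolecular folding), an
annotated repeat overlap, or DNA depth exceeding three times the
sample's peak (modal) depth in any DNA sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import rc_local_align
from .pileup import Pileup
from .types import GeneModel, GenomeSeq, RepeatLocus


@dataclass
class AntisenseVerdict:
    chrom: str
    pos: int
    strand: str
    both_strand_transcription: bool = False
    opposite_editing: bool = False
    intramolecular_rc: bool = False
    repeat_overlap: bool = False
    dna_depth_peak: bool = False

    @property
    def is_candidate(self) -> bool:
        return (
            self.both_strand_transcription
            and self.opposite_editing
            and not (self.intramolecular_rc or self.repeat_overlap or self.dna_depth_peak)
        )


def both_strand_transcription_test(
    chrom: str, pos: int, rna: Pileup, window_half: int = 50, min_depth: int = 2,
    min_fraction: float = 0.5,
) -> bool:
    """Depth >= 2 along > 50% of the 101-nt window on both strands.

    Windows clipped at chromosome ends are renormalized to their length.
    """
    L = rna.genome.length(chrom)
    lo = max(0, pos - window_half)
    hi = min(L, pos + window_half + 1)
    n = hi - lo
    for strand in "+-":
        covered = int((rna.depth(chrom, strand)[lo:hi] >= min_depth).sum())
        if not covered / n > min_fraction:
            return False
    return True


def opposite_editing_test(
    chrom: str, pos: int, strand: str, sites: pd.DataFrame, window_half: int = 25
) -> bool:
    """>= 1 A-to-I site on the opposite strand within +/- ``window_half`` nt."""
    opp = "-" if strand == "+" else "+"
    sub = sites[
        (sites["chrom"] == chrom)
        & (sites["strand"] == opp)
        & (sites["pos"] >= pos - window_half)
        & (sites["pos"] <= pos + window_half)
    ]
    return len(sub) > 0


def intramolecular_exclusion(
    chrom: str, pos: int, genome: GenomeSeq,
    query_half: int = 200, window_half: int = 2000,
    min_identity: float = 0.8, min_len: int = 20,
) -> bool:
    """True (excluded) iff a qualifying reverse-complement self-alignment exists."""
    arr = genome[chrom]
    q_lo = max(0, pos - query_half)
    q_hi = min(len(arr), pos + query_half + 1)
    w_lo = max(0, pos - window_half)
    w_hi = min(len(arr), pos + window_half + 1)
    aln = rc_local_align(
        arr[q_lo:q_hi], arr[w_lo:w_hi],
        min_identity=min_identity, min_len=min_len, must_span=pos - q_lo,
    )
    return aln is not None


def peak_depth(dna: Pileup, chrom: str | None = None, method: str = "mode") -> int:
    """Peak (modal) depth of covered positions across the DNA pileup."""
    depths = []
    for c in dna.genome:
        if chrom is not None and c != chrom:
            continue
        d = dna.depth(c)
        depths.append(d[d > 0])
    alld = np.concatenate(depths) if depths else np.empty(0, int)
    if len(alld) == 0:
        return 0
    if method == "median":
        return int(np.median(alld))
    return int(np.bincount(alld).argmax())


def repeat_and_depth_exclusion(
    chrom: str, pos: int,
    repeats: list[RepeatLocus],
    dna_pileups: dict[str, Pileup],
    peak_depths: dict[str, int],
    depth_factor: float = 3.0,
) -> tuple[bool, bool]:
    """(repeat_overlap, dna_depth_peak) exclusion flags for one site.

    The depth exclusion is strict: depth must exceed ``depth_factor`` x
    the sample's modal depth (exactly 3x is retained).
    """
    in_repeat = any(r.interval.contains(chrom, pos) for r in repeats)
    depth_bad = False
    for sid, dna in dna_pileups.items():
        if dna.depth(chrom)[pos] > depth_factor * peak_depths[sid]:
            depth_bad = True
            break
    return in_repeat, depth_bad


def classify_sites(
    sites: pd.DataFrame,
    rna_pileups: dict[str, Pileup],
    dna_pileups: dict[str, Pileup],
    genome: GenomeSeq,
    repeats: list[RepeatLocus],
) -> list[AntisenseVerdict]:
    """Run the full cascade on every A-to-I site of the species editome.

    Both-strand transcription is satisfied when any sample's stranded
    RNA pileup satisfies it (the dsRNA must exist in some sample).
    """
    peaks = {sid: peak_depth(p) for sid, p in dna_pileups.items()}
    ai = sites[sites["type"] == "A-to-G"]
    out = []
    for r in ai.itertuples(index=False):
        v = AntisenseVerdict(r.chrom, r.pos, r.strand)
        v.both_strand_transcription = any(
            both_strand_transcription_test(r.chrom, r.pos, p)
            for p in rna_pileups.values()
        )
        v.opposite_editing = opposite_editing_test(r.chrom, r.pos, r.strand, ai)
        if v.both_strand_transcription and v.opposite_editing:
            v.intramolecular_rc = intramolecular_exclusion(r.chrom, r.pos, genome)
            v.repeat_overlap, v.dna_depth_peak = repeat_and_depth_exclusion(
                r.chrom, r.pos, repeats, dna_pileups, peaks
            )
        out.append(v)
    return out


def verdicts_to_frame(verdicts: list[AntisenseVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                v.chrom, v.pos, v.strand,
                v.both_strand_transcription, v.opposite_editing,
                v.intramolecular_rc, v.repeat_overlap, v.dna_depth_peak,
                v.is_candidate,
            )
            for v in verdicts
        ],
        columns=[
            "chrom", "pos", "strand",
            "both_strand_transcription", "opposite_editing",
            "intramolecular_rc", "repeat_overlap", "dna_depth_peak",
            "candidate",
        ],
    )


def summarize_pairs(
    verdicts: list[AntisenseVerdict],
    genes: list[GeneModel],
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group candidate sites into opposite-strand gene-pair loci.

    Each candidate site is assigned to the gene whose span contains it on
    its own strand; the overlapping gene on the opposite strand completes
    the pair.  Returns one row per pair with per-gene site counts.
    """
    cands = [v for v in verdicts if v.is_candidate]
    pair_sites: dict[tuple[str, str], dict[str, int]] = {}
    for v in cands:
        own = [
            g for g in genes
            if g.strand == v.strand and g.span.contains(v.chrom, v.pos)
        ]
        opp = [
            g for g in genes
            if g.strand != v.strand and g.span.contains(v.chrom, v.pos)
        ]
        if not own or not opp:
            continue
        ga, gb = own[0], opp[0]
        plus, minus = (ga, gb) if ga.strand == "+" else (gb, ga)
        key = (plus.gene_id, minus.gene_id)
        d = pair_sites.setdefault(key, {"+": 0, "-": 0})
        d[v.strand] += 1
    rows = [
        (plus, minus, d["+"], d["-"], d["+"] + d["-"])
        for (plus, minus), d in sorted(pair_sites.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_plus", "gene_minus", "sites_plus", "sites_minus", "sites_total"],
    )
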