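"""Strand-aware pileup construction from ungapped aligned reads.

RNA pileups are stranded: each base is attributed to the transcribed
strand of its read under the dUTP rule (mate 2 carries the original
transcript strand, so a mate-1 read mapped forward counts toward the
minus strand).  DNA pileups are unstranded.  Bases below the quality
floor and reads below the mapping-quality floor are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .types import AlignedRead, GenomeSeq

STRAND_IDX = {"+": 0, "-": 1}


@dataclass
class PileupColumn:
    """Per-position base counts from the DNA and stranded RNA pileups."""

    chrom: str
    pos: int
    dna_counts: dict[str, int]
    rna_counts_fwd: dict[str, int]
    rna_counts_rev: dict[str, int]
    min_baseq: int


@dataclass
class Pileup:
    """Per-chromosome base-count arrays.

    ``counts[chrom]`` has shape (5, L) for an unstranded pileup and
    (2, 5, L) for a stranded one (axis 0: transcribed strand +/-; axis
    -2: base codes A,C,G,T,N).  N bases are never counted.
    """

    genome: GenomeSeq
    stranded: bool
    min_baseq: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_reads: int = 0
    n_rejected: int = 0
    retained_bases: int = 0

    def __post_init__(self):
        shape = (2, 4) if self.stranded else (4,)
        for c in self.genome:
            self.counts[c] = np.zeros(shape + (self.genome.length(c),), dtype=np.int32)

    def add_read(self, read: AlignedRead, min_mapq: int, read2_sense: bool = True) -> bool:
        if read.mapq < min_mapq:
            self.n_rejected += 1
            return False
        if read.chrom not in self.counts or read.end > self.genome.length(read.chrom):
            self.n_rejected += 1
            return False
        keep = (read.quals >= self.min_baseq) & (read.codes < 4)
        pos = np.arange(read.start, read.end)[keep]
        codes = read.codes[keep]
        arr = self.counts[read.chrom]
        if self.stranded:
            s = STRAND_IDX[read.transcript_strand(read2_sense)]
            np.add.at(arr[s], (codes, pos), 1)
        else:
            np.add.at(arr, (codes, pos), 1)
        self.n_reads += 1
        self.retained_bases += int(keep.sum())
        return True

    # ------------------------------------------------------------ accessors

    def depth(self, chrom: str, strand: str | None = None) -> np.ndarray:
        """Per-position depth over A,C,G,T (int32 array of length L)."""
        arr = self.counts[chrom]
        if self.stranded:
            if strand is None:
                return arr.sum(axis=(0, 1), dtype=np.int64).astype(np.int64)
            return arr[STRAND_IDX[strand]].sum(axis=0)
        return arr.sum(axis=0)

    def base_counts(self, chrom: str, pos: int, strand: str | None = None) -> dict[str, int]:
        arr = self.counts[chrom]
        if self.stranded:
            if strand is None:
                col = arr[:, :, pos].sum(axis=0)
            else:
                col = arr[STRAND_IDX[strand], :, pos]
        else:
            col = arr[:, pos]
        return {b: int(col[i]) for i, b in enumerate("ACGT")}

    def total_bases(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))


def build_pileup(
    reads: Iterable[AlignedRead],
    genome: GenomeSeq,
    min_baseq: int = 30,
    min_mapq: int = 20,
    stranded: bool = False,
    read2_sense: bool = True,
) -> Pileup:
    pile = Pileup(genome, stranded=stranded, min_baseq=min_baseq)
    for read in reads:
        pile.add_read(read, min_mapq=min_mapq, read2_sense=read2_sense)
    return pile


def pileup_column(
    chrom: str, pos: int, dna: Pileup, rna: Pileup
) -> PileupColumn:
    return PileupColumn(
        chrom=chrom,
        pos=pos,
        dna_counts=dna.base_counts(chrom, pos),
        rna_counts_fwd=rna.base_counts(chrom, pos, "+"),
        rna_counts_rev=rna.base_counts(chrom, pos, "-"),
        min_baseq=rna.min_baseq,
    )
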