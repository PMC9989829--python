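"""Shared domain types for the editome pipeline.

Coordinates are 0-based half-open internally; emitted tables are 1-based
inclusive.  ``strand`` is one of ``+``, ``-``, ``.``; for editing sites the
strand is the transcribed strand and ``ref_base``/``edited_base`` are given
on that strand (a T->C mismatch in reference coordinates on a minus-strand
transcript is an A-to-G site with strand ``-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Helitron", "tandem", "unclassified")

#: the 12 possible single-nucleotide substitution types, transcribed-strand
SUBST_TYPES = tuple(
    f"{a}-to-{b}" for a in "ACGT" for b in "ACGT" if a != b
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement_base(b: str) -> str:
    return _COMP[b]


def _rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def subst_type(ref_base: str, edited_base: str) -> str:
    st = f"{ref_base}-to-{edited_base}"
    if st not in SUBST_TYPES:
        raise ValueError(f"invalid substitution {ref_base}->{edited_base}")
    return st


class GenomeSeq:
    """A haploid reference genome: chromosome name -> uint8 code array."""

    def __init__(self, sequences: dict[str, np.ndarray]):
        if len(set(sequences)) != len(sequences):
            raise ValueError("duplicate chromosome names")
        for name, codes in sequences.items():
            if len(codes) == 0:
                raise ValueError(f"empty sequence for record {name!r}")
        self.sequences = dict(sequences)

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "GenomeSeq":
        return cls({name: _seq.encode(s) for name, s in seqs.items()})

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def string(self, chrom: str) -> str:
        return _seq.decode(self.sequences[chrom])

    def copy(self) -> "GenomeSeq":
        return GenomeSeq({c: s.copy() for c, s in self.sequences.items()})

    def base(self, chrom: str, pos: int, strand: str = "+") -> str:
        b = _seq.BASES[self.sequences[chrom][pos]]
        return b if strand != "-" else complement_base(b)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class RepeatLocus:
    interval: Interval
    repeat_class: str
    divergence: float

    def __post_init__(self):
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")


@dataclass
class GeneModel:
    """A protein-coding gene, genome-collinear (no trans-splicing).

    ``exons``, ``cds``, ``utr5``, ``utr3`` and ``introns`` are sorted,
    non-overlapping interval lists; UTR/CDS/intron partitions the
    transcribed span and total CDS length is a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    introns: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return Interval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    def cds_in_transcript_order(self) -> list[Interval]:
        return sorted(
            self.cds, key=lambda iv: iv.start, reverse=self.strand == "-"
        )

    def coding_sequence(self, chrom_codes: np.ndarray) -> str:
        """The spliced coding sequence on the coding strand."""
        parts = []
        for iv in self.cds_in_transcript_order():
            seg = _seq.decode(chrom_codes[iv.start : iv.end])
            parts.append(_rc(seg) if self.strand == "-" else seg)
        return "".join(parts)

    def coding_to_genome(self, cpos: int) -> int:
        """Map a 0-based coding-sequence position to a genome position."""
        off = 0
        for iv in self.cds_in_transcript_order():
            if cpos < off + len(iv):
                i = cpos - off
                return iv.start + i if self.strand == "+" else iv.end - 1 - i
            off += len(iv)
        raise IndexError(f"coding position {cpos} outside CDS of {self.gene_id}")

    def genome_to_coding(self, pos: int) -> int | None:
        """Map a genome position to a coding-sequence position (None if non-CDS)."""
        off = 0
        for iv in self.cds_in_transcript_order():
            if iv.start <= pos < iv.end:
                i = pos - iv.start if self.strand == "+" else iv.end - 1 - pos
                return off + i
            off += len(iv)
        return None

    def validate(self) -> None:
        if self.cds_length() % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        parts = sorted(
            self.cds + self.utr5 + self.utr3 + self.introns,
            key=lambda iv: iv.start,
        )
        for a, b in zip(parts, parts[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.gene_id}: overlapping segments")
            if a.end != b.start:
                raise ValueError(f"{self.gene_id}: gap in transcribed span")
        if parts and (parts[0].start, parts[-1].end) != (
            self.span.start,
            self.span.end,
        ):
            raise ValueError(f"{self.gene_id}: segments do not cover the span")


@dataclass
class EditingCluster:
    """A maximal run of >= 3 editing sites with adjacent gaps <= 30 nt.

    The cluster's genomic start/end are the first and last member sites.
    """

    chrom: str
    members: np.ndarray  # sorted site positions

    @property
    def start(self) -> int:
        return int(self.members[0])

    @property
    def end(self) -> int:
        return int(self.members[-1])

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AlignedRead:
    """One ungapped aligned mate, stored in reference-forward orientation."""

    read_id: str
    mate: int  # 1 or 2
    chrom: str
    start: int
    strand: str  # mapping strand of this mate
    mapq: int
    codes: np.ndarray  # uint8 base codes as aligned to the forward reference
    quals: np.ndarray  # Phred scores, same length

    def __post_init__(self):
        if len(self.codes) != len(self.quals):
            raise ValueError("sequence/quality length mismatch")

    @property
    def end(self) -> int:
        return self.start + len(self.codes)

    def transcript_strand(self, read2_sense: bool = True) -> str:
        """Transcribed-strand assignment under the dUTP rule.

        With the dUTP chemistry mate 2 carries the original transcript
        strand; ``read2_sense=False`` flips the rule for the opposite
        chemistry.
        """
        sense_mate = 2 if read2_sense else 1
        if self.mate == sense_mate:
            return self.strand
        return "-" if self.strand == "+" else "+"


@dataclass
class EditingSite:
    chrom: str
    pos: int  # 0-based
    strand: str  # transcribed strand
    ref_base: str  # on the transcribed strand
    edited_base: str  # on the transcribed strand
    dna_depth: int
    rna_edited: int
    rna_total: int
    sample_id: str
    provenance: str  # standard | hyper | recovered

    def __post_init__(self):
        if self.rna_edited > self.rna_total:
            raise ValueError("rna_edited > rna_total")
        if self.provenance not in ("standard", "hyper", "recovered"):
            raise ValueError(f"bad provenance {self.provenance!r}")

    @property
    def subst_type(self) -> str:
        return subst_type(self.ref_base, self.edited_base)

    @property
    def editing_level(self) -> float:
        return self.rna_edited / self.rna_total if self.rna_total else 0.0

    @property
    def ref_base_fwd(self) -> str:
        """Reference base in forward genome coordinates."""
        return self.ref_base if self.strand != "-" else complement_base(self.ref_base)

    @property
    def edited_base_fwd(self) -> str:
        return (
            self.edited_base
            if self.strand != "-"
            else complement_base(self.edited_base)
        )
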