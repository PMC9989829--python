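"""Hyper-editing detection via three-letter transformed alignment.

Heavily edited reads carry too many same-type mismatches to survive the
standard alignment.  For each of the 12 substitution types X-to-Y the
scheme collapses the edited base pair: mate 2 (the transcript-strand
read under the dUTP chemistry) and the *positive* reference collapse
X->Y, while mate 1 and the *negative* reference collapse
complement(X)->complement(Y).  Transformed pairs are aligned to both
references; concordant pairs with the stated per-reference orientation
(positive: mate 1 reverse-complement, mate 2 direct; negative: mirrored)
and both MAPQ >= 20 are untransformed, trimmed by 10 nt at each end, and
judged hyper-edited when the trimmed mismatch rate exceeds 5% with more
than 60% of mismatches of the expected type.  Sites are then extracted
from the hyper reads alone (support >= 2, no level floor) and the 12
per-type site sets are combined, discarding positions claimed by more
than one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .align import UngappedAligner
from .pileup import build_pileup
from .sitecall import GenotypeCalls, call_candidate_sites
from .types import AlignedRead, EditingSite, GenomeSeq

SUBST_12 = tuple(f"{a}-to-{b}" for a in "ACGT" for b in "ACGT" if a != b)


@dataclass
class HyperCandidatePair:
    """A read pair harvested from the standard alignment's rejects."""

    read_id: str
    codes1: np.ndarray  # sequenced orientation
    quals1: np.ndarray
    codes2: np.ndarray
    quals2: np.ndarray
    reason: str  # "unaligned" | "mapq_lt_20"


@dataclass
class HyperAlignment:
    read: AlignedRead  # untransformed, reference-forward orientation
    trim_start: int  # offset of the trimmed span within the read
    trim_len: int
    mismatches: int
    expected_mismatches: int
    verdict: bool


@dataclass
class HyperStageSummary:
    harvested: int = 0
    prefiltered: int = 0
    per_type: dict[str, dict[str, int]] = field(default_factory=dict)


def _parse_subst(subst: str) -> tuple[int, int]:
    if subst not in SUBST_12:
        raise ValueError(f"unknown substitution type {subst!r}")
    x, y = subst.split("-to-")
    return _seq.BASES.index(x), _seq.BASES.index(y)


def _collapse(codes: np.ndarray, x: int, y: int) -> np.ndarray:
    out = codes.copy()
    out[out == x] = y
    return out


def transform_read(codes: np.ndarray, mate: int, subst: str) -> np.ndarray:
    """Three-letter transform of a sequenced read for one substitution type."""
    x, y = _parse_subst(subst)
    if mate == 2:
        return _collapse(codes, x, y)
    if mate == 1:
        return _collapse(codes, int(_seq.COMPLEMENT[x]), int(_seq.COMPLEMENT[y]))
    raise ValueError(f"mate must be 1 or 2, got {mate}")


def transform_reference(genome: GenomeSeq, subst: str) -> tuple[GenomeSeq, GenomeSeq]:
    """(positive, negative) references: X->Y and comp(X)->comp(Y) collapsed."""
    x, y = _parse_subst(subst)
    pos = GenomeSeq({c: _collapse(genome[c], x, y) for c in genome})
    neg = GenomeSeq(
        {
            c: _collapse(genome[c], int(_seq.COMPLEMENT[x]), int(_seq.COMPLEMENT[y]))
            for c in genome
        }
    )
    return pos, neg


def prefilter_pair(pair: HyperCandidatePair) -> bool:
    """True if the pair survives the composition prefilter.

    A pair is removed when either mate has >10% N, or any single
    nucleotide making up >60% or <10% of its length.
    """
    for codes in (pair.codes1, pair.codes2):
        L = len(codes)
        if L == 0:
            return False
        if np.count_nonzero(codes == 4) / L > 0.10:
            return False
        for b in range(4):
            f = np.count_nonzero(codes == b) / L
            if f > 0.60 or f < 0.10:
                return False
    return True


def align_transformed(
    pairs: list[HyperCandidatePair],
    genome: GenomeSeq,
    subst: str,
    max_mm: int = 6,
    k: int = 13,
    max_insert: int = 1000,
    min_mapq: int = 20,
) -> list[tuple[HyperCandidatePair, AlignedRead, AlignedRead, str]]:
    """Concordantly align transformed pairs to the positive/negative references.

    Returns (pair, untransformed mate1, untransformed mate2, which_ref)
    for pairs placed uniquely on exactly one reference (reads placed
    equally well on both are discarded as ambiguous).  The returned
    AlignedReads carry the *original* (untransformed) sequences in
    reference-forward orientation.
    """
    ref_pos, ref_neg = transform_reference(genome, subst)
    al_pos = UngappedAligner(ref_pos, k=k)
    al_neg = UngappedAligner(ref_neg, k=k)
    out = []
    for pair in pairs:
        t1 = transform_read(pair.codes1, 1, subst)
        t2 = transform_read(pair.codes2, 2, subst)
        # positive reference: mate1 reverse-complement, mate2 direct
        hp = al_pos.align_pair(
            t1, t2, max_mm=max_mm, max_insert=max_insert,
            required_strand1="-", required_strand2="+",
        )
        # negative reference: mate1 direct, mate2 reverse-complement
        hn = al_neg.align_pair(
            t1, t2, max_mm=max_mm, max_insert=max_insert,
            required_strand1="+", required_strand2="-",
        )
        cand = []
        if hp is not None and hp.mapq1 >= min_mapq and hp.mapq2 >= min_mapq:
            cand.append(("positive", hp))
        if hn is not None and hn.mapq1 >= min_mapq and hn.mapq2 >= min_mapq:
            cand.append(("negative", hn))
        if not cand:
            continue
        if len(cand) == 2:
            if cand[0][1].total_mismatches == cand[1][1].total_mismatches:
                continue  # exact tie between references: discard
            cand.sort(key=lambda t: t[1].total_mismatches)
        which, hit = cand[0]
        reads = []
        for mate, codes, quals, h in (
            (1, pair.codes1, pair.quals1, hit.hit1),
            (2, pair.codes2, pair.quals2, hit.hit2),
        ):
            if h.strand == "-":
                fwd_codes = _seq.revcomp_codes(codes)
                fwd_quals = quals[::-1]
            else:
                fwd_codes, fwd_quals = codes, quals
            reads.append(
                AlignedRead(pair.read_id, mate, h.chrom, h.start, h.strand, 37,
                            fwd_codes, fwd_quals)
            )
        out.append((pair, reads[0], reads[1], which))
    return out


def score_hyper_read(
    read: AlignedRead, genome: GenomeSeq, subst: str, which_ref: str,
    trim: int = 10, min_trimmed_len: int = 21,
    min_rate: float = 0.05, min_expected_fraction: float = 0.60,
) -> HyperAlignment | None:
    """Judge one untransformed read against the untransformed genome.

    The first and last ``trim`` bases are dropped; the verdict is true
    iff the trimmed mismatch rate is strictly > ``min_rate`` and the
    expected-type share of mismatches strictly > ``min_expected_fraction``.
    """
    L = len(read.codes)
    tl = L - 2 * trim
    if tl < min_trimmed_len:
        return None
    ref = genome[read.chrom][read.start + trim : read.start + trim + tl]
    obs = read.codes[trim : trim + tl]
    mm = (obs != ref) & (obs < 4) & (ref < 4)
    x, y = _parse_subst(subst)
    if which_ref == "negative":
        x, y = int(_seq.COMPLEMENT[x]), int(_seq.COMPLEMENT[y])
    exp = mm & (ref == x) & (obs == y)
    n_mm = int(mm.sum())
    n_exp = int(exp.sum())
    verdict = (n_mm / tl > min_rate) and (n_mm > 0 and n_exp / n_mm > min_expected_fraction)
    return HyperAlignment(read, trim, tl, n_mm, n_exp, verdict)


def extract_hyper_sites(
    hyper_reads: list[AlignedRead],
    genome: GenomeSeq,
    genotypes: GenotypeCalls,
    sample_id: str,
    min_support: int = 2,
    min_baseq: int = 30,
    read2_sense: bool = True,
) -> list[EditingSite]:
    """Call sites from hyper-verdict reads (support >= 2, level floor 0)."""
    pile = build_pileup(
        (_trimmed(r) for r in hyper_reads),
        genome,
        min_baseq=min_baseq,
        min_mapq=20,
        stranded=True,
        read2_sense=read2_sense,
    )
    return call_candidate_sites(
        pile, genotypes, sample_id, min_support=min_support, min_level=0.0,
        provenance="hyper",
    )


def _trimmed(read: AlignedRead, trim: int = 10) -> AlignedRead:
    return AlignedRead(
        read.read_id, read.mate, read.chrom, read.start + trim, read.strand,
        read.mapq, read.codes[trim : len(read.codes) - trim],
        read.quals[trim : len(read.quals) - trim],
    )


def combine_twelve_types(
    per_type: dict[str, list[EditingSite]]
) -> list[EditingSite]:
    """Union of the 12 per-type site sets, dropping multi-type positions."""
    by_key: dict[tuple, EditingSite] = {}
    types_at_pos: dict[tuple, set[str]] = {}
    for sites in per_type.values():
        for s in sites:
            types_at_pos.setdefault((s.chrom, s.pos), set()).add(s.subst_type)
            key = (s.chrom, s.pos, s.strand, s.subst_type)
            prev = by_key.get(key)
            if prev is None or s.rna_edited > prev.rna_edited:
                by_key[key] = s
    out = [
        s
        for key, s in by_key.items()
        if len(types_at_pos[(s.chrom, s.pos)]) == 1
    ]
    out.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return out


def run_hyper_stage(
    candidates: list[HyperCandidatePair],
    genome: GenomeSeq,
    genotypes: GenotypeCalls,
    sample_id: str,
    subst_types: tuple[str, ...] = SUBST_12,
    max_mm: int = 6,
    read2_sense: bool = True,
) -> tuple[list[EditingSite], HyperStageSummary]:
    """Run the full hyper-editing detection cascade for one sample."""
    summary = HyperStageSummary(harvested=len(candidates))
    kept = [p for p in candidates if prefilter_pair(p)]
    summary.prefiltered = len(candidates) - len(kept)
    per_type: dict[str, list[EditingSite]] = {}
    for subst in subst_types:
        placed = align_transformed(kept, genome, subst, max_mm=max_mm)
        hyper_reads = []
        n_verdict = 0
        for _pair, r1, r2, which in placed:
            for rd in (r1, r2):
                ha = score_hyper_read(rd, genome, subst, which)
                if ha is not None and ha.verdict:
                    hyper_reads.append(rd)
                    n_verdict += 1
        sites = extract_hyper_sites(
            hyper_reads, genome, genotypes, sample_id, read2_sense=read2_sense
        )
        per_type[subst] = sites
        summary.per_type[subst] = {
            "aligned_pairs": len(placed),
            "hyper_reads": n_verdict,
            "sites": len(sites),
        }
    combined = combine_twelve_types(per_type)
    return combined, summary
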