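"""Per-sample editing-site calling from matched DNA/RNA pileups.

The DNA data first yields per-position genotype calls with a frequency
threshold (homozygous when the major allele carries >= ``hom_fraction``
of >= ``min_depth`` bases).  The reference is then adjusted so that
homozygous differences from the assembly (strain variants) do not
masquerade as RNA edits, and candidate sites are emitted wherever a
homozygous position shows exactly one alternative base on a transcribed
strand with enough support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .pileup import Pileup
from .types import EditingSite, GenomeSeq, complement_base

NOCALL, HOM, HET = 0, 1, 2


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int
    call: str  # "hom" | "het" | "nocall"
    genotype_base: str | None
    dna_depth: int
    major_fraction: float


@dataclass
class GenotypeCalls:
    """Vectorized per-chromosome genotype arrays."""

    call: dict[str, np.ndarray]  # int8: NOCALL/HOM/HET
    base: dict[str, np.ndarray]  # uint8 major-allele code (valid where called)
    depth: dict[str, np.ndarray]
    major_fraction: dict[str, np.ndarray]

    def at(self, chrom: str, pos: int) -> GenotypeCall:
        code = int(self.call[chrom][pos])
        return GenotypeCall(
            chrom,
            pos,
            {NOCALL: "nocall", HOM: "hom", HET: "het"}[code],
            _seq.BASES[self.base[chrom][pos]] if code != NOCALL else None,
            int(self.depth[chrom][pos]),
            float(self.major_fraction[chrom][pos]),
        )

    def is_hom(self, chrom: str, pos: int) -> bool:
        return self.call[chrom][pos] == HOM


def call_genotypes(
    dna: Pileup, min_depth: int = 10, hom_fraction: float = 0.95
) -> GenotypeCalls:
    call, base, depth, frac = {}, {}, {}, {}
    for chrom, cnt in dna.counts.items():
        d = cnt.sum(axis=0)
        major = cnt.argmax(axis=0).astype(np.uint8)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(d > 0, cnt.max(axis=0) / np.maximum(d, 1), 0.0)
        c = np.full(len(d), NOCALL, dtype=np.int8)
        covered = d >= min_depth
        c[covered & (f >= hom_fraction)] = HOM
        c[covered & (f < hom_fraction)] = HET
        call[chrom], base[chrom], depth[chrom], frac[chrom] = c, major, d, f
    return GenotypeCalls(call, base, depth, frac)


def adjust_reference(
    genome: GenomeSeq, genotypes: GenotypeCalls
) -> tuple[GenomeSeq, list[tuple[str, int, str, str]]]:
    """Replace reference bases that disagree with a homozygous DNA consensus.

    Only single-base substitutions are made, so coordinates are unchanged.
    Returns the adjusted genome and a change log of (chrom, pos, old, new).
    """
    out = genome.copy()
    changes: list[tuple[str, int, str, str]] = []
    for chrom in genome:
        ref = out[chrom]
        hom = genotypes.call[chrom] == HOM
        diff = hom & (genotypes.base[chrom] != ref) & (ref < 4)
        for pos in np.flatnonzero(diff):
            old = _seq.BASES[ref[pos]]
            new = _seq.BASES[genotypes.base[chrom][pos]]
            ref[pos] = genotypes.base[chrom][pos]
            changes.append((chrom, int(pos), old, new))
    return out, changes


def call_candidate_sites(
    rna: Pileup,
    genotypes: GenotypeCalls,
    sample_id: str,
    min_support: int = 3,
    min_level: float = 0.05,
    provenance: str = "standard",
) -> list[EditingSite]:
    """Emit candidate sites: homozygous DNA, one alternative RNA base.

    A site is called per (position, transcribed strand) where the strand
    shows exactly one distinct base differing from the homozygous
    genotype, with >= ``min_support`` supporting reads and an editing
    level >= ``min_level``.  Positions with more than one distinct
    alternative base on the strand are discarded.
    """
    sites: list[EditingSite] = []
    for chrom, arr in rna.counts.items():  # (2, 4, L)
        hom = genotypes.call[chrom] == HOM
        gbase = genotypes.base[chrom]
        ddep = genotypes.depth[chrom]
        L = arr.shape[-1]
        idx = np.arange(L)
        for sidx, strand in ((0, "+"), (1, "-")):
            cnt = arr[sidx]
            total = cnt.sum(axis=0)
            refc = cnt[gbase, idx]
            altc = cnt.copy()
            altc[gbase, idx] = 0
            n_alt_kinds = (altc > 0).sum(axis=0)
            alt_base = altc.argmax(axis=0).astype(np.uint8)
            alt_count = altc.max(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                level = np.where(total > 0, alt_count / np.maximum(total, 1), 0.0)
            ok = (
                hom
                & (n_alt_kinds == 1)
                & (alt_count >= min_support)
                & (level >= min_level)
            )
            for pos in np.flatnonzero(ok):
                ref_b = _seq.BASES[gbase[pos]]
                alt_b = _seq.BASES[alt_base[pos]]
                if strand == "-":
                    ref_b, alt_b = complement_base(ref_b), complement_base(alt_b)
                sites.append(
                    EditingSite(
                        chrom=chrom,
                        pos=int(pos),
                        strand=strand,
                        ref_base=ref_b,
                        edited_base=alt_b,
                        dna_depth=int(ddep[pos]),
                        rna_edited=int(alt_count[pos]),
                        rna_total=int(total[pos]),
                        sample_id=sample_id,
                        provenance=provenance,
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return sites
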