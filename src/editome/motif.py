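"""Neighboring-nucleotide preference of A-to-I editing (two-sample style).

Foreground: 11-mers centered on edited adenosines, read on the
transcribed strand (reverse-complemented for minus-strand sites).
Background: 11-mers centered on transcribed (depth >= 2) but unedited
adenosines within +/- 50 nt of an edited adenosine, deduplicated by
position.  Per (position, nucleotide) cell, the foreground count is
tested two-sided against the background frequency with an exact binomial
test, BH-corrected across the 40 non-center cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from ._seq import A, T
from .pileup import Pileup
from .stats import binom_test_two_sided, fdr_adjust
from .types import GenomeSeq

FLANK = 5  # positions -5..+5
VECTOR_ORDER = [
    (p, b) for p in range(-FLANK, FLANK + 1) if p != 0 for b in "ACGT"
]


@dataclass
class MotifProfile:
    fg_counts: np.ndarray  # (11, 4) position x base
    bg_counts: np.ndarray
    n_fg: int
    n_bg: int

    def freq_diff(self) -> np.ndarray:
        fg = self.fg_counts / max(self.n_fg, 1)
        bg = self.bg_counts / max(self.n_bg, 1)
        return fg - bg


def _collect_kmers(
    genome: GenomeSeq, positions: list[tuple[str, int, str]], flank: int = FLANK
) -> tuple[np.ndarray, int]:
    counts = np.zeros((2 * flank + 1, 4), dtype=np.int64)
    n = 0
    for chrom, pos, strand in positions:
        arr = genome[chrom]
        if pos - flank < 0 or pos + flank + 1 > len(arr):
            continue  # too close to a contig end
        win = arr[pos - flank : pos + flank + 1]
        if strand == "-":
            win = _seq.revcomp_codes(win)
        ok = win < 4
        counts[np.flatnonzero(ok), win[ok]] += 1
        n += 1
    return counts, n


def background_adenosines(
    sites: pd.DataFrame, rna: Pileup, genome: GenomeSeq,
    window_half: int = 50, min_depth: int = 2,
) -> list[tuple[str, int, str]]:
    """Transcribed unedited adenosines within +/-50 nt of edited ones."""
    edited = set(zip(sites["chrom"], sites["pos"]))
    out: dict[tuple[str, int], str] = {}
    by_chrom: dict[str, list] = {}
    for r in sites.itertuples(index=False):
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    for chrom, poss in by_chrom.items():
        arr = genome[chrom]
        L = len(arr)
        near = np.zeros(L, bool)
        for p in poss:
            near[max(0, p - window_half) : min(L, p + window_half + 1)] = True
        for strand, base in (("+", A), ("-", T)):
            dep = rna.depth(chrom, strand)
            cand = np.flatnonzero(near & (arr == base) & (dep >= min_depth))
            for p in cand:
                if (chrom, int(p)) not in edited:
                    out.setdefault((chrom, int(p)), strand)
    return [(c, p, s) for (c, p), s in sorted(out.items())]


def build_motif_profile(
    sites: pd.DataFrame, rna: Pileup, genome: GenomeSeq
) -> MotifProfile:
    fg_pos = [
        (r.chrom, r.pos, r.strand)
        for r in sites.itertuples(index=False)
    ]
    bg_pos = background_adenosines(sites, rna, genome)
    fg, n_fg = _collect_kmers(genome, fg_pos)
    bg, n_bg = _collect_kmers(genome, bg_pos)
    return MotifProfile(fg, bg, n_fg, n_bg)


def position_tests(profile: MotifProfile, fdr: float = 0.01) -> pd.DataFrame:
    """Per-cell exact binomial tests of foreground counts vs background freq.

    Cells whose background frequency is 0 or 1 are skipped (logged via
    NaN p-values).  BH correction runs across the 40 non-center cells.
    """
    rows = []
    fg_tot, bg_tot = max(profile.n_fg, 1), max(profile.n_bg, 1)
    for p, b in VECTOR_ORDER:
        i = p + FLANK
        j = "ACGT".index(b)
        bg_freq = profile.bg_counts[i, j] / bg_tot
        fg_freq = profile.fg_counts[i, j] / fg_tot
        if bg_freq in (0.0, 1.0):
            pval = np.nan
        else:
            pval = binom_test_two_sided(int(profile.fg_counts[i, j]), profile.n_fg, bg_freq)
        rows.append((p, b, int(profile.fg_counts[i, j]), int(profile.bg_counts[i, j]),
                     fg_freq, bg_freq, fg_freq - bg_freq, pval))
    df = pd.DataFrame(
        rows,
        columns=["position", "base", "fg_count", "bg_count",
                 "fg_freq", "bg_freq", "diff", "p_value"],
    )
    tested = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.values] = fdr_adjust(df.loc[tested, "p_value"].values)
    df["q_value"] = q
    df["significant"] = (df["q_value"] < fdr) & tested
    df["direction"] = np.sign(df["diff"]).astype(int)
    return df


def preference_vector(profile: MotifProfile) -> np.ndarray:
    """Flat 40-cell frequency-difference vector (position-major, A<C<G<T)."""
    diff = profile.freq_diff()
    return np.asarray(
        [diff[p + FLANK, "ACGT".index(b)] for p, b in VECTOR_ORDER]
    )
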