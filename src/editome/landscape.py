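"""Genomic characterization of the editome.

Covers element annotation of sites, editing-cluster identification
(>= 3 same-type sites with adjacent gaps <= 30 nt), depth-matched
control-site sampling, editability (A-to-I sites per million transcribed
adenosines per element class, plain and editing-level-weighted),
repeat-divergence binning, and the dsRNA-forming potential of repeat vs
non-repeat regions via nearby reverse-complement alignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _seq
from ._seq import A, T
from .align import rc_local_align
from .pileup import Pileup
from .types import EditingCluster  # noqa: F401  (re-exported)
from .types import GeneModel, GenomeSeq, RepeatLocus

GENE_CLASSES = ("5UTR", "CDS", "intron", "3UTR")
SINGLE_LABEL_PRECEDENCE = ("repeat", "CDS", "5UTR", "3UTR", "intron", "intergenic")


# ------------------------------------------------------------------ masks


def element_masks(
    genome: GenomeSeq,
    repeats: list[RepeatLocus],
    genes: list[GeneModel],
) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome boolean masks for every element class."""
    masks: dict[str, dict[str, np.ndarray]] = {}
    for chrom in genome:
        L = genome.length(chrom)
        m = {cls: np.zeros(L, bool) for cls in GENE_CLASSES}
        m.update({cls: np.zeros(L, bool) for cls in set(r.repeat_class for r in repeats)})
        m["repeat"] = np.zeros(L, bool)
        m["genic"] = np.zeros(L, bool)
        masks[chrom] = m
    for r in repeats:
        iv = r.interval
        masks[iv.chrom][r.repeat_class][iv.start : iv.end] = True
        masks[iv.chrom]["repeat"][iv.start : iv.end] = True
    for g in genes:
        m = masks[g.chrom]
        for iv in g.utr5:
            m["5UTR"][iv.start : iv.end] = True
        for iv in g.cds:
            m["CDS"][iv.start : iv.end] = True
        for iv in g.utr3:
            m["3UTR"][iv.start : iv.end] = True
        for iv in g.introns:
            m["intron"][iv.start : iv.end] = True
        sp = g.span
        m["genic"][sp.start : sp.end] = True
    return masks


def annotate_sites(
    sites: pd.DataFrame, masks: dict[str, dict[str, np.ndarray]]
) -> pd.DataFrame:
    """Label each site with all overlapping element classes.

    ``labels`` holds every co-occurring class (a genic site inside a SINE
    keeps both, as the concurrent-repeat view needs); ``single_label``
    applies the precedence repeat > CDS > UTR > intron > intergenic.
    """
    labels, single = [], []
    classes_by_chrom = {
        c: [k for k in m if k not in ("repeat", "genic")] for c, m in masks.items()
    }
    for r in sites.itertuples(index=False):
        m = masks[r.chrom]
        labs = sorted(k for k in classes_by_chrom[r.chrom] if m[k][r.pos])
        if not labs:
            labs = ["intergenic"]
        labels.append(",".join(labs))
        if m["repeat"][r.pos]:
            single.append("repeat")
        else:
            for cls in ("CDS", "5UTR", "3UTR", "intron"):
                if m[cls][r.pos]:
                    single.append(cls)
                    break
            else:
                single.append("intergenic")
    out = sites.copy()
    out["labels"] = labels
    out["single_label"] = single
    return out


# ------------------------------------------------------------------ clusters


def find_clusters(
    positions_by_chrom: dict[str, np.ndarray],
    max_gap: int = 30,
    min_size: int = 3,
) -> tuple[list[EditingCluster], float]:
    """Maximal runs of sites with adjacent gaps <= max_gap and >= min_size.

    Returns the clusters and the clustered fraction (clustered sites over
    all sites).  Strand is ignored: clusters are genomic regions.
    """
    clusters: list[EditingCluster] = []
    n_total = n_clustered = 0
    for chrom in sorted(positions_by_chrom):
        pos = np.sort(np.unique(np.asarray(positions_by_chrom[chrom], dtype=np.int64)))
        n_total += len(pos)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            if e - s >= min_size:
                members = pos[s:e]
                clusters.append(EditingCluster(chrom, members))
                n_clustered += len(members)
    frac = n_clustered / n_total if n_total else 0.0
    return clusters, frac


# ------------------------------------------------------------------ controls


def sample_control_sites(
    sites: pd.DataFrame,
    rna: Pileup,
    genome: GenomeSeq,
    seed: int,
    depth_tolerance: float = 0.2,
) -> pd.DataFrame:
    """One random transcribed adenosine per editing site, depth-matched.

    The control has the site's transcribed-strand RNA depth within
    +/- ``depth_tolerance``, is not itself an edited position, and is
    drawn without replacement.  Sites with no eligible control are
    skipped (logged via the returned frame's site count being smaller).
    """
    rng = np.random.default_rng(seed)
    edited = set(zip(sites["chrom"], sites["pos"]))
    pools: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome:
        arr = genome[chrom]
        for strand, base in (("+", A), ("-", T)):
            cand = np.flatnonzero(arr == base)
            depth = rna.depth(chrom, strand)[cand]
            keep = depth >= 1
            cand, depth = cand[keep], depth[keep]
            order = np.argsort(depth, kind="stable")
            pools[(chrom, strand)] = (cand[order], depth[order])
    taken: set[tuple[str, int]] = set()
    rows = []
    for r in sites.itertuples(index=False):
        pool_pos, pool_depth = pools[(r.chrom, r.strand)]
        d = rna.depth(r.chrom, r.strand)[r.pos]
        lo = np.searchsorted(pool_depth, d * (1 - depth_tolerance), "left")
        hi = np.searchsorted(pool_depth, d * (1 + depth_tolerance), "right")
        idxs = np.arange(lo, hi)
        rng.shuffle(idxs)
        for i in idxs:
            p = int(pool_pos[i])
            if (r.chrom, p) in edited or (r.chrom, p) in taken:
                continue
            taken.add((r.chrom, p))
            rows.append((r.chrom, p, r.strand, int(pool_depth[i]), r.pos))
            break
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "depth", "matched_site_pos"]
    )


# ------------------------------------------------------------------ editability


def _transcribed_adenosines(
    genome: GenomeSeq, rna: Pileup, chrom: str, min_depth: int
) -> dict[str, np.ndarray]:
    """Boolean per-strand masks of transcribed adenosines on a chromosome."""
    arr = genome[chrom]
    out = {}
    for strand, base in (("+", A), ("-", T)):
        out[strand] = (arr == base) & (rna.depth(chrom, strand) >= min_depth)
    return out


def editability(
    sites: pd.DataFrame,
    rna: Pileup,
    genome: GenomeSeq,
    masks: dict[str, dict[str, np.ndarray]],
    classes: list[str],
    weighted: bool = False,
    min_depth: int | None = None,
) -> pd.DataFrame:
    """Editing density per element class for one sample.

    Plain: sites per million transcribed adenosines (RNA depth >= 2 on
    the adenosine's strand).  Weighted: each site contributes its editing
    level, and only sites / adenosines at depth >= 10 count.  Classes
    with zero transcribed adenosines get a missing (NaN) density.
    """
    if min_depth is None:
        min_depth = 10 if weighted else 2
    rows = []
    tr = {c: _transcribed_adenosines(genome, rna, c, min_depth) for c in genome}
    for cls in classes:
        n_aden = 0
        for chrom in genome:
            if cls not in masks[chrom]:
                continue
            m = masks[chrom][cls]
            n_aden += int((m & tr[chrom]["+"]).sum() + (m & tr[chrom]["-"]).sum())
        weight = 0.0
        for r in sites.itertuples(index=False):
            if cls not in masks[r.chrom] or not masks[r.chrom][cls][r.pos]:
                continue
            if weighted:
                if r.rna_total >= min_depth:
                    weight += r.level
            else:
                weight += 1.0
        density = weight / n_aden * 1e6 if n_aden else np.nan
        rows.append((cls, weight, n_aden, density))
    return pd.DataFrame(
        rows, columns=["element", "n_sites", "n_transcribed_adenosines", "density_per_million"]
    )


# ------------------------------------------------------------------ divergence


def transcribed_repeat_loci(
    repeats: list[RepeatLocus], rna: Pileup, min_covered: int = 50, min_depth: int = 2
) -> list[RepeatLocus]:
    """Repeat loci with >= ``min_covered`` nt at total RNA depth >= ``min_depth``."""
    out = []
    for r in repeats:
        iv = r.interval
        d = rna.depth(iv.chrom)[iv.start : iv.end]
        if int((d >= min_depth).sum()) >= min_covered:
            out.append(r)
    return out


def divergence_bins(
    sites: pd.DataFrame,
    repeats: list[RepeatLocus],
    rna: Pileup,
    genome: GenomeSeq,
    n_bins: int = 10,
    min_depth: int = 2,
) -> pd.DataFrame:
    """Editing density in equal-count bins of repeat divergence (one sample).

    Transcribed loci are sorted by divergence ascending (ties broken by
    coordinate) and split into ``n_bins`` equal-count bins; each bin's
    density is its sites per million transcribed adenosines.
    """
    loci = transcribed_repeat_loci(repeats, rna, min_depth=min_depth)
    if len(loci) < n_bins:
        raise ValueError(
            f"only {len(loci)} transcribed repeat loci; use a bin count <= {len(loci)}"
        )
    loci.sort(key=lambda r: (r.divergence, r.interval.chrom, r.interval.start))
    tr = {c: _transcribed_adenosines(genome, rna, c, min_depth) for c in genome}
    site_pos = {}
    for r in sites.itertuples(index=False):
        site_pos.setdefault(r.chrom, []).append(r.pos)
    site_pos = {c: np.sort(np.asarray(v)) for c, v in site_pos.items()}
    rows = []
    for b, chunk in enumerate(np.array_split(np.arange(len(loci)), n_bins)):
        n_sites = 0
        n_aden = 0
        divs = []
        for i in chunk:
            iv = loci[i].interval
            divs.append(loci[i].divergence)
            n_aden += int(
                tr[iv.chrom]["+"][iv.start : iv.end].sum()
                + tr[iv.chrom]["-"][iv.start : iv.end].sum()
            )
            if iv.chrom in site_pos:
                p = site_pos[iv.chrom]
                n_sites += int(
                    np.searchsorted(p, iv.end) - np.searchsorted(p, iv.start)
                )
        density = n_sites / n_aden * 1e6 if n_aden else np.nan
        rows.append((b, float(np.mean(divs)), len(chunk), n_sites, n_aden, density))
    return pd.DataFrame(
        rows,
        columns=["bin", "mean_divergence", "n_loci", "n_sites",
                 "n_transcribed_adenosines", "density_per_million"],
    )


# ------------------------------------------------------------------ dsRNA


def dsrna_forming_potential(
    genome: GenomeSeq,
    repeats: list[RepeatLocus],
    n_sites: int = 100_000,
    reps: int = 100,
    seed: int = 0,
    query_half: int = 200,
    window_half: int = 2000,
    min_identity: float = 0.8,
    min_len: int = 50,
) -> pd.DataFrame:
    """Fraction of random sites with a nearby reverse-complement alignment.

    For repeat-derived and non-repeat-derived random sites separately, a
    401-nt query centered on the site is searched against the 4001-nt
    window centered on it; the site counts when an alignment with
    identity >= 80%, length >= 50 nt and spanning the site exists.
    Repeated ``reps`` times for a ratio distribution.  Windows are
    clipped at chromosome ends and the site retained.
    """
    rng = np.random.default_rng(seed)
    rep_pos, nonrep_pos = [], []
    for chrom in genome:
        L = genome.length(chrom)
        mask = np.zeros(L, bool)
        for r in repeats:
            if r.interval.chrom == chrom:
                mask[r.interval.start : r.interval.end] = True
        idx = np.arange(L)
        rep_pos.append((chrom, idx[mask]))
        nonrep_pos.append((chrom, idx[~mask]))
    rows = []
    for rep_i in range(reps):
        for cls, pools in (("repeat", rep_pos), ("non_repeat", nonrep_pos)):
            sizes = np.asarray([len(p) for _, p in pools])
            if sizes.sum() == 0:
                rows.append((rep_i, cls, n_sites, np.nan))
                continue
            take = rng.multinomial(n_sites, sizes / sizes.sum())
            n_hit = 0
            for (chrom, pool), k in zip(pools, take):
                if k == 0:
                    continue
                arr = genome[chrom]
                picks = pool[rng.integers(0, len(pool), k)]
                for p in picks:
                    q_lo = max(0, p - query_half)
                    q_hi = min(len(arr), p + query_half + 1)
                    w_lo = max(0, p - window_half)
                    w_hi = min(len(arr), p + window_half + 1)
                    aln = rc_local_align(
                        arr[q_lo:q_hi],
                        arr[w_lo:w_hi],
                        min_identity=min_identity,
                        min_len=min_len,
                        must_span=p - q_lo,
                    )
                    if aln is not None:
                        n_hit += 1
            rows.append((rep_i, cls, n_sites, n_hit / n_sites))
    return pd.DataFrame(rows, columns=["rep", "class", "n_sites", "ratio"])
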