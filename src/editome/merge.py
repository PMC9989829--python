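"""Combining standard and hyper calls, cross-sample recovery and filters.

Per sample, sites found by the standard and hyper passes are unioned;
where both found a site the edited / non-edited read supports are added.
The union of all samples' sites defines the species map of editable
positions; samples lacking a call at an editable position recover it
when at least one Q>=30 RNA read supports editing and the BH-adjusted
binomial sequencing-error p-value (B(k, n, p), p = 0.001) is < 0.01,
with the adjustment taken over all recovery candidates within the
sample.  Species-level filters then remove positions whose edited base
appears at > 10% frequency in any sample's DNA, and positions showing
different substitution types in different samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pileup import Pileup
from .stats import binomial_upper_tail, fdr_adjust
from .types import EditingSite, complement_base

EDITOME_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "type",
    "sample",
    "dna_depth",
    "rna_edited",
    "rna_total",
    "level",
    "provenance",
]


@dataclass
class SpeciesEditome:
    """Long-format editome: one row per (site, sample) observation."""

    df: pd.DataFrame
    filter_log: list[dict] = field(default_factory=list)

    @property
    def sites(self) -> pd.DataFrame:
        """One row per unique (chrom, pos, strand) with pooled statistics."""
        if self.df.empty:
            return pd.DataFrame(
                columns=["chrom", "pos", "strand", "type", "n_samples",
                         "sum_edited", "sum_total", "mean_level"]
            )
        g = self.df.groupby(["chrom", "pos", "strand"], sort=True)
        out = g.agg(
            type=("type", "first"),
            n_samples=("sample", "nunique"),
            sum_edited=("rna_edited", "sum"),
            sum_total=("rna_total", "sum"),
            mean_level=("level", "mean"),
        ).reset_index()
        return out

    def to_wide(self) -> pd.DataFrame:
        """Wide per-sample table (edited/total/level columns per sample)."""
        if self.df.empty:
            return pd.DataFrame()
        piv = self.df.pivot_table(
            index=["chrom", "pos", "strand", "type"],
            columns="sample",
            values=["rna_edited", "rna_total", "level"],
            aggfunc="first",
        )
        piv.columns = [f"{v}_{s}" for v, s in piv.columns]
        return piv.reset_index().sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def merge_sample_calls(
    standard: list[EditingSite], hyper: list[EditingSite]
) -> tuple[list[EditingSite], list[dict]]:
    """Union the two passes for one sample, adding supports where both hit.

    Positions claimed with different substitution types by the two passes
    are dropped and logged.
    """
    dropped: list[dict] = []
    by_key: dict[tuple, EditingSite] = {
        (s.chrom, s.pos, s.strand): s for s in standard
    }
    out: dict[tuple, EditingSite] = dict(by_key)
    for h in hyper:
        key = (h.chrom, h.pos, h.strand)
        s = out.get(key)
        if s is None:
            out[key] = h
            continue
        if s.subst_type != h.subst_type:
            del out[key]
            dropped.append(
                {"chrom": h.chrom, "pos": h.pos, "strand": h.strand,
                 "reason": "type_conflict_between_passes",
                 "standard": s.subst_type, "hyper": h.subst_type}
            )
            continue
        out[key] = EditingSite(
            chrom=s.chrom, pos=s.pos, strand=s.strand,
            ref_base=s.ref_base, edited_base=s.edited_base,
            dna_depth=max(s.dna_depth, h.dna_depth),
            rna_edited=s.rna_edited + h.rna_edited,
            rna_total=s.rna_total + h.rna_total,
            sample_id=s.sample_id, provenance="standard",
        )
    merged = sorted(out.values(), key=lambda s: (s.chrom, s.pos, s.strand))
    return merged, dropped


def build_editome(per_sample: dict[str, list[EditingSite]]) -> SpeciesEditome:
    rows = [
        (
            s.chrom, s.pos, s.strand, s.subst_type, sid,
            s.dna_depth, s.rna_edited, s.rna_total, s.editing_level, s.provenance,
        )
        for sid, sites in per_sample.items()
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=EDITOME_COLUMNS)
    df = df.sort_values(["chrom", "pos", "strand", "sample"]).reset_index(drop=True)
    return SpeciesEditome(df)


def recover_missed_sites(
    editome: SpeciesEditome,
    rna_pileups: dict[str, Pileup],
    dna_pileups: dict[str, Pileup],
    error_p: float = 0.001,
    fdr: float = 0.01,
) -> SpeciesEditome:
    """Recover sites missed per sample at editable positions (BH q < fdr).

    Candidates are all (editable position, sample) combinations without a
    call where the expected edited base has >= 1 supporting read; the BH
    adjustment spans all such candidates within the sample.
    """
    sites = editome.sites
    have = set(map(tuple, editome.df[["chrom", "pos", "strand", "sample"]].values))
    new_rows = []
    for sid, rna in rna_pileups.items():
        cand = []
        for r in sites.itertuples(index=False):
            if (r.chrom, r.pos, r.strand, sid) in have:
                continue
            edited_t = r.type.split("-to-")[1]
            edited_fwd = (
                edited_t if r.strand == "+" else complement_base(edited_t)
            )
            counts = rna.base_counts(r.chrom, r.pos, r.strand)
            n = sum(counts.values())
            k = counts[edited_fwd]
            if k >= 1:
                cand.append((r, k, n))
        if not cand:
            continue
        pvals = binomial_upper_tail(
            np.asarray([k for _, k, _ in cand]),
            np.asarray([n for _, _, n in cand]),
            error_p,
        )
        qvals = fdr_adjust(np.atleast_1d(pvals))
        for (r, k, n), q in zip(cand, qvals):
            if q < fdr:
                dna = dna_pileups[sid].base_counts(r.chrom, r.pos)
                new_rows.append(
                    (r.chrom, r.pos, r.strand, r.type, sid,
                     sum(dna.values()), k, n, k / n, "recovered")
                )
    if new_rows:
        add = pd.DataFrame(new_rows, columns=EDITOME_COLUMNS)
        df = pd.concat([editome.df, add], ignore_index=True)
        df = df.sort_values(["chrom", "pos", "strand", "sample"]).reset_index(drop=True)
        return SpeciesEditome(df, editome.filter_log)
    return editome


def dna_variant_filter(
    editome: SpeciesEditome, dna_pileups: dict[str, Pileup], max_freq: float = 0.1
) -> SpeciesEditome:
    """Drop sites whose edited base exceeds ``max_freq`` in any sample's DNA."""
    if editome.df.empty:
        return editome
    drop_keys = set()
    log = list(editome.filter_log)
    for r in editome.sites.itertuples(index=False):
        edited_t = r.type.split("-to-")[1]
        edited_fwd = edited_t if r.strand == "+" else complement_base(edited_t)
        for sid, dna in dna_pileups.items():
            counts = dna.base_counts(r.chrom, r.pos)
            total = sum(counts.values())
            if total and counts[edited_fwd] / total > max_freq:
                drop_keys.add((r.chrom, r.pos, r.strand))
                log.append(
                    {"chrom": r.chrom, "pos": r.pos, "strand": r.strand,
                     "reason": "dna_variant", "sample": sid,
                     "freq": counts[edited_fwd] / total}
                )
                break
    if not drop_keys:
        return SpeciesEditome(editome.df, log)
    mask = [
        (c, p, s) not in drop_keys
        for c, p, s in editome.df[["chrom", "pos", "strand"]].itertuples(index=False)
    ]
    return SpeciesEditome(editome.df[mask].reset_index(drop=True), log)


def cross_sample_conflict_filter(editome: SpeciesEditome) -> SpeciesEditome:
    """Drop genomic positions showing different substitution types anywhere."""
    if editome.df.empty:
        return editome
    ntypes = editome.df.groupby(["chrom", "pos"])["type"].nunique()
    bad = set(ntypes[ntypes > 1].index)
    log = list(editome.filter_log)
    for c, p in sorted(bad):
        log.append({"chrom": c, "pos": p, "reason": "cross_sample_type_conflict"})
    mask = [
        (c, p) not in bad
        for c, p in editome.df[["chrom", "pos"]].itertuples(index=False)
    ]
    return SpeciesEditome(editome.df[mask].reset_index(drop=True), log)
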