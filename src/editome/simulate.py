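"""Synthetic matched DNA/RNA data with planted A-to-I editing truth.

The generator emulates the data model the pipeline assumes: a diploid
genome with heterozygous SNPs and homozygous strain differences, repeat
families including nearby inverted copies of tunable divergence, intron-
containing protein-coding genes (some arranged as overlapping antiparallel
sense-antisense pairs), dUTP-protocol strand-specific paired RNA reads,
and planted A-to-I edits in five categories: isolated sites, clustered
sites (co-edited on single molecules, so heavily edited reads fail the
standard alignment), hyper-edited regions, recoding sites in CDS, and
both-strand-edited antisense overlaps.

All randomness flows from ``numpy.random.default_rng`` seeded from the
recipe; the same recipe yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from . import _seq, io
from ._seq import A, C, G, T
from .types import AlignedRead, GeneModel, GenomeSeq, Interval, RepeatLocus

STOP_CODONS = {"TAA", "TAG", "TGA"}


# ------------------------------------------------------------------ recipe


@dataclass
class RepeatFamilySpec:
    repeat_class: str
    unit_length: int
    n_copies: int
    inverted_fraction: float  # fraction of copies arranged as nearby inverted pairs
    divergence: float  # per-copy substitution rate from the family consensus


@dataclass
class ClusterSpec:
    count: int = 50
    sites_per_cluster: int = 6
    span: int = 60
    level: float = 0.7  # fraction of molecules edited at every member site


@dataclass
class HyperSpec:
    count: int = 4
    region_length: int = 150
    level: float = 0.5  # fraction of molecules that are hyper-edited
    per_read_fraction: float = 0.35  # fraction of As edited on such a molecule


@dataclass
class SimulationRecipe:
    """Study conditions for one synthetic species."""

    seed: int = 0
    genome_length: int = 200_000
    chrom_name: str = "chr1"
    n_samples: int = 3

    # sequencing
    read_length: int = 100
    fragment_mean: int = 260
    fragment_sd: int = 25
    dna_depth: float = 30.0
    rna_depth: float = 30.0
    error_rate: float = 0.001  # per-base error at Q>=30
    lowq_fraction: float = 0.02  # bases emitted at Q15 with 10% error

    # genetics
    het_snps: int = 300
    hom_diffs: int = 100  # homozygous strain differences vs the reference

    # annotation
    n_genes: int = 20
    gene_utr5: int = 200
    gene_cds: int = 900
    gene_intron: int = 150
    gene_utr3: int = 450
    antisense_pairs: int = 3
    antisense_overlap: int = 400
    antisense_end_margin: int = 120  # keep planted sites out of the 3' coverage ramp
    repeat_families: list[RepeatFamilySpec] = field(
        default_factory=lambda: [
            RepeatFamilySpec("SINE", 300, 30, 0.4, 0.08),
            RepeatFamilySpec("LINE", 400, 16, 0.25, 0.15),
            RepeatFamilySpec("tandem", 200, 10, 0.0, 0.05),
        ]
    )
    transcribed_repeat_fraction: float = 0.8
    repeat_divergence_decay: float = 10.0  # site weight ~ exp(-decay * divergence)

    # planted truth
    isolated_sites: int = 200
    isolated_level_range: tuple[float, float] = (0.2, 0.8)
    isolated_repeat_fraction: float = 0.6
    clusters: ClusterSpec = field(default_factory=ClusterSpec)
    hyper: HyperSpec = field(default_factory=HyperSpec)
    recoding_sites: int = 12
    recoding_level_range: tuple[float, float] = (0.2, 0.6)
    antisense_sites_per_strand: int = 4
    antisense_level_range: tuple[float, float] = (0.35, 0.65)
    motif_u_bias: float = 0.8  # probability the 5' neighbor of a planted edit is U

    def validate(self) -> None:
        for name in (
            "transcribed_repeat_fraction",
            "isolated_repeat_fraction",
            "motif_u_bias",
            "error_rate",
            "lowq_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dna_depth < 1 or self.rna_depth < 1:
            raise ValueError("depths must be >= 1")
        if self.gene_cds % 3 != 0:
            raise ValueError("gene_cds must be a multiple of 3")

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationRecipe":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["repeat_families"] = [RepeatFamilySpec(**f) for f in d["repeat_families"]]
        d["clusters"] = ClusterSpec(**d["clusters"])
        d["hyper"] = HyperSpec(**d["hyper"])
        for key in ("isolated_level_range", "recoding_level_range", "antisense_level_range"):
            d[key] = tuple(d[key])
        return cls(**d)


class RecipeError(ValueError):
    pass


def divergence_trend_recipe(seed: int) -> SimulationRecipe:
    """Study conditions for the repeat-divergence / editability analysis.

    Five same-class repeat families spanning divergences 0.02-0.26, all
    transcribed, with isolated edits placed only in repeats at a density
    decaying in divergence (weight ~ exp(-10 d)); no clusters or hyper
    regions, so the binned densities reflect the planted decay alone.
    """
    fams = [
        RepeatFamilySpec("SINE", 300, 12, 0.0, d)
        for d in (0.02, 0.08, 0.14, 0.20, 0.26)
    ]
    r = SimulationRecipe(
        seed=seed, genome_length=60_000, n_samples=1, n_genes=2,
        antisense_pairs=0, repeat_families=fams,
        transcribed_repeat_fraction=1.0,
        isolated_sites=150, isolated_repeat_fraction=1.0,
        het_snps=0, hom_diffs=0, recoding_sites=0,
    )
    r.clusters = ClusterSpec(count=0)
    r.hyper = HyperSpec(count=0)
    return r


def inverted_repeat_recipe(seed: int, inverted: bool = True) -> SimulationRecipe:
    """A genome rich in nearby inverted repeat pairs (or repeat-free).

    Used by the dsRNA-forming-potential analysis: with ``inverted`` every
    repeat copy belongs to a low-divergence inverted pair, so nearly all
    repeat-derived sites sit in fold-back-capable regions; without it the
    genome is plain random sequence.
    """
    fams = [RepeatFamilySpec("SINE", 300, 60, 1.0, 0.02)] if inverted else []
    r = SimulationRecipe(
        seed=seed, genome_length=100_000, n_genes=0, antisense_pairs=0,
        repeat_families=fams, isolated_sites=0, recoding_sites=0,
        het_snps=0, hom_diffs=0,
    )
    r.clusters = ClusterSpec(count=0)
    r.hyper = HyperSpec(count=0)
    return r


# ------------------------------------------------------------------ truth


@dataclass
class PlantedEvent:
    chrom: str
    pos: int
    strand: str
    level: float
    category: str  # isolated | recoding | antisense | cluster | hyper


@dataclass
class CorrelatedRegion:
    """A region whose member edits co-occur on single RNA molecules."""

    chrom: str
    start: int
    end: int
    strand: str
    level: float  # fraction of molecules that are editing molecules
    per_site_prob: float  # per covered member site, within an editing molecule
    members: np.ndarray  # sorted member positions
    category: str  # cluster | hyper


@dataclass
class Truth:
    events: list[PlantedEvent]
    regions: list[CorrelatedRegion]
    het_snps: list[tuple[str, int, str, str]]  # chrom, pos, ref, alt
    hom_diffs: list[tuple[str, int, str, str]]

    def site_frame(self) -> pd.DataFrame:
        rows = [
            (e.chrom, e.pos + 1, e.strand, "A-to-G", round(e.level, 4), e.category)
            for e in self.events
        ]
        for r in self.regions:
            lvl = r.level * r.per_site_prob
            rows.extend(
                (r.chrom, int(p) + 1, r.strand, "A-to-G", round(lvl, 4), r.category)
                for p in r.members
            )
        df = pd.DataFrame(
            rows, columns=["chrom", "pos_1based", "strand", "type", "level", "category"]
        )
        return df.sort_values(["chrom", "pos_1based", "strand"]).reset_index(drop=True)

    def snp_frame(self) -> pd.DataFrame:
        rows = [(c, p + 1, r, a, "het") for c, p, r, a in self.het_snps]
        rows += [(c, p + 1, r, a, "hom") for c, p, r, a in self.hom_diffs]
        df = pd.DataFrame(rows, columns=["chrom", "pos_1based", "ref", "alt", "kind"])
        return df.sort_values(["chrom", "pos_1based"]).reset_index(drop=True)


@dataclass
class SimGenome:
    genome: GenomeSeq
    repeats: list[RepeatLocus]
    genes: list[GeneModel]
    transcription_units: list[Interval]  # gene exons plus noncoding repeat transcripts
    noncoding_tx: list[Interval]
    antisense_gene_pairs: list[tuple[str, str]]

    @property
    def chrom(self) -> str:
        return next(iter(self.genome))


# ------------------------------------------------------------------ genome


def _coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    bases = "ACGT"
    while len(codons) < n_codons - 2:
        cdn = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if cdn not in STOP_CODONS:
            codons.append(cdn)
    return "ATG" + "".join(codons) + "TAA"


def _build_gene(
    gene_id: str, chrom: str, x: int, strand: str, recipe: SimulationRecipe
) -> GeneModel:
    u5, cds, intr, u3 = (
        recipe.gene_utr5,
        recipe.gene_cds,
        recipe.gene_intron,
        recipe.gene_utr3,
    )
    c1 = (cds // 6) * 3
    c2 = cds - c1
    g = GeneModel(gene_id, chrom, strand)
    if strand == "+":
        parts = [("utr5", u5), ("cds", c1), ("intron", intr), ("cds", c2), ("utr3", u3)]
    else:
        parts = [("utr3", u3), ("cds", c2), ("intron", intr), ("cds", c1), ("utr5", u5)]
    pos = x
    for kind, ln in parts:
        iv = Interval(chrom, pos, pos + ln, strand)
        getattr(g, {"utr5": "utr5", "utr3": "utr3", "cds": "cds", "intron": "introns"}[kind]).append(iv)
        pos += ln
    sp_start, sp_end = x, pos
    intron = g.introns[0]
    g.exons = [
        Interval(chrom, sp_start, intron.start, strand),
        Interval(chrom, intron.end, sp_end, strand),
    ]
    g.validate()
    return g


def _write_cds(genome_arr: np.ndarray, gene: GeneModel, coding: str) -> None:
    """Write a coding sequence into the genome along the gene's CDS segments."""
    segs = sorted(gene.cds, key=lambda iv: iv.start, reverse=gene.strand == "-")
    off = 0
    for iv in segs:
        ln = len(iv)
        chunk = coding[off : off + ln]
        if gene.strand == "-":
            genome_arr[iv.start : iv.end] = _seq.encode(_seq.revcomp(chunk))
        else:
            genome_arr[iv.start : iv.end] = _seq.encode(chunk)
        off += ln


def _mutate_copy(rng: np.random.Generator, codes: np.ndarray, rate: float) -> tuple[np.ndarray, float]:
    out = codes.copy()
    n_sub = rng.binomial(len(codes), rate)
    if n_sub:
        pos = rng.choice(len(codes), size=n_sub, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, n_sub)) % 4
    return out, n_sub / len(codes)


def simulate_genome(recipe: SimulationRecipe) -> SimGenome:
    recipe.validate()
    rng = np.random.default_rng([recipe.seed, 11])
    L = recipe.genome_length
    chrom = recipe.chrom_name
    arr = rng.integers(0, 4, L, dtype=np.uint8)

    gene_len = (
        recipe.gene_utr5 + recipe.gene_cds + recipe.gene_intron + recipe.gene_utr3
    )
    margin = 120

    blocks: list[tuple[str, object, int]] = []  # (kind, payload, length)
    n_pair_genes = 2 * recipe.antisense_pairs
    if recipe.n_genes < n_pair_genes:
        raise RecipeError("n_genes smaller than 2 * antisense_pairs")
    for i in range(recipe.n_genes - n_pair_genes):
        blocks.append(("gene", i, gene_len))
    for i in range(recipe.antisense_pairs):
        blocks.append(("aspair", i, 2 * gene_len - recipe.antisense_overlap))

    consensi = {
        fam.repeat_class: rng.integers(0, 4, fam.unit_length, dtype=np.uint8)
        for fam in recipe.repeat_families
    }
    for fam in recipe.repeat_families:
        n_pairs = int(round(fam.n_copies * fam.inverted_fraction / 2))
        n_single = fam.n_copies - 2 * n_pairs
        for _ in range(n_pairs):
            gap = int(rng.integers(80, 400))
            blocks.append(("invpair", (fam, gap), 2 * fam.unit_length + gap))
        for _ in range(n_single):
            blocks.append(("repeat", fam, fam.unit_length))

    need = sum(b[2] for b in blocks) + margin * (len(blocks) + 1)
    if need > L:
        raise RecipeError(
            f"requested features need {need} nt but the genome is only {L} nt"
        )
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    slack = L - sum(b[2] for b in blocks) - margin * (len(blocks) + 1)
    extra = rng.multinomial(slack, np.full(len(blocks) + 1, 1.0 / (len(blocks) + 1)))

    genes: list[GeneModel] = []
    repeats: list[RepeatLocus] = []
    noncoding: list[Interval] = []
    as_pairs: list[tuple[str, str]] = []
    pos = margin + int(extra[0])
    gid = 0
    for bi, (kind, payload, ln) in enumerate(blocks):
        if kind == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            g = _build_gene(f"gene{gid:03d}", chrom, pos, strand, recipe)
            gid += 1
            _write_cds(arr, g, _coding_seq(rng, recipe.gene_cds // 3))
            genes.append(g)
        elif kind == "aspair":
            ga = _build_gene(f"gene{gid:03d}", chrom, pos, "+", recipe)
            gid += 1
            gb = _build_gene(
                f"gene{gid:03d}",
                chrom,
                pos + gene_len - recipe.antisense_overlap,
                "-",
                recipe,
            )
            gid += 1
            _write_cds(arr, ga, _coding_seq(rng, recipe.gene_cds // 3))
            _write_cds(arr, gb, _coding_seq(rng, recipe.gene_cds // 3))
            genes.append(ga)
            genes.append(gb)
            as_pairs.append((ga.gene_id, gb.gene_id))
        elif kind == "repeat":
            fam = payload
            copy, div = _mutate_copy(rng, consensi[fam.repeat_class], fam.divergence)
            arr[pos : pos + ln] = copy
            repeats.append(
                RepeatLocus(Interval(chrom, pos, pos + ln, "."), fam.repeat_class, div)
            )
            if rng.random() < recipe.transcribed_repeat_fraction:
                s = "+" if rng.random() < 0.5 else "-"
                noncoding.append(
                    Interval(chrom, max(0, pos - 60), min(L, pos + ln + 60), s)
                )
        else:  # invpair
            fam, gap = payload
            cons = consensi[fam.repeat_class]
            c1, d1 = _mutate_copy(rng, cons, fam.divergence)
            c2, d2 = _mutate_copy(rng, _seq.revcomp_codes(cons), fam.divergence)
            u = fam.unit_length
            arr[pos : pos + u] = c1
            arr[pos + u + gap : pos + 2 * u + gap] = c2
            repeats.append(
                RepeatLocus(Interval(chrom, pos, pos + u, "."), fam.repeat_class, d1)
            )
            repeats.append(
                RepeatLocus(
                    Interval(chrom, pos + u + gap, pos + 2 * u + gap, "."),
                    fam.repeat_class,
                    d2,
                )
            )
            if rng.random() < recipe.transcribed_repeat_fraction:
                s = "+" if rng.random() < 0.5 else "-"
                noncoding.append(
                    Interval(chrom, max(0, pos - 60), min(L, pos + ln + 60), s)
                )
        pos += ln + margin + int(extra[bi + 1])

    genes.sort(key=lambda g: g.span.start)
    repeats.sort(key=lambda r: r.interval.start)
    units = [
        Interval(g.chrom, e.start, e.end, g.strand) for g in genes for e in g.exons
    ] + noncoding
    units.sort(key=lambda iv: (iv.start, iv.strand))
    return SimGenome(
        genome=GenomeSeq({chrom: arr}),
        repeats=repeats,
        genes=genes,
        transcription_units=units,
        noncoding_tx=noncoding,
        antisense_gene_pairs=as_pairs,
    )


# ------------------------------------------------------------------ truth planting


def _strand_base_positions(
    arr: np.ndarray, unit: Interval, base_code: int
) -> np.ndarray:
    """Genome positions inside ``unit`` whose transcribed-strand base is ``base_code``."""
    want = base_code if unit.strand == "+" else int(_seq.COMPLEMENT[base_code])
    sub = arr[unit.start : unit.end]
    return unit.start + np.flatnonzero(sub == want)


def _u5_mask(arr: np.ndarray, positions: np.ndarray, strand: str) -> np.ndarray:
    """True where the 5'-neighboring base (on the transcribed strand) is U(T)."""
    if strand == "+":
        prev = positions - 1
        ok = prev >= 0
        out = np.zeros(len(positions), bool)
        out[ok] = arr[prev[ok]] == T
    else:
        nxt = positions + 1
        ok = nxt < len(arr)
        out = np.zeros(len(positions), bool)
        out[ok] = arr[nxt[ok]] == A  # complement(A) = U on the minus strand
    return out


def _biased_pick(
    rng: np.random.Generator,
    positions: np.ndarray,
    u5: np.ndarray,
    k: int,
    bias: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sample k positions without replacement, biasing the 5'-U context."""
    if weights is None:
        weights = np.ones(len(positions))
    w = weights.astype(float).copy()
    w[u5] *= bias / 0.25
    w[~u5] *= (1.0 - bias) / 0.75
    if w.sum() <= 0 or len(positions) < k:
        raise RecipeError("not enough candidate adenosines to plant the requested edits")
    idx = rng.choice(len(positions), size=k, replace=False, p=w / w.sum())
    return positions[np.sort(idx)]


def plant_truth(sim: SimGenome, recipe: SimulationRecipe) -> Truth:
    rng = np.random.default_rng([recipe.seed, 23])
    arr = sim.genome[sim.chrom]
    chrom = sim.chrom
    used: set[int] = set()
    events: list[PlantedEvent] = []
    regions: list[CorrelatedRegion] = []

    def _lrange(rr):
        return rr[0] + (rr[1] - rr[0]) * rng.random()

    # --- antisense overlaps: an alternating-strand chain of edits so every
    # site has an opposite-strand site within the 51-nt window
    gene_by_id = {g.gene_id: g for g in sim.genes}
    for ga_id, gb_id in sim.antisense_gene_pairs:
        ga, gb = gene_by_id[ga_id], gene_by_id[gb_id]
        ov_start = max(ga.span.start, gb.span.start)
        ov_end = min(ga.span.end, gb.span.end)
        lo = ov_start + recipe.antisense_end_margin
        hi = ov_end - recipe.antisense_end_margin
        if hi - lo < 40:
            raise RecipeError("antisense overlap too short for the end margin")
        cur = lo
        strand = "+"
        placed_chain = 0
        want_total = 2 * recipe.antisense_sites_per_strand
        while placed_chain < want_total and cur < hi:
            base = A if strand == "+" else T
            rel = np.flatnonzero(arr[cur:hi] == base)
            rel = [x for x in rel if cur + x not in used]
            if not rel:
                break
            p = cur + int(rel[0])
            events.append(
                PlantedEvent(
                    chrom, p, strand, _lrange(recipe.antisense_level_range), "antisense"
                )
            )
            used.add(p)
            placed_chain += 1
            cur = p + 10
            strand = "-" if strand == "+" else "+"
        if placed_chain < want_total:
            raise RecipeError("could not place the requested antisense edits")

    # --- recoding sites: nonsynonymous A>G in CDS on the coding strand
    candidates = []
    for g in sim.genes:
        coding = g.coding_sequence(arr)
        n_codons = len(coding) // 3
        for ci in range(1, n_codons - 1):
            codon = coding[3 * ci : 3 * ci + 3]
            for cp in range(3):
                if codon[cp] != "A":
                    continue
                edited = codon[:cp] + "G" + codon[cp + 1 :]
                if edited in STOP_CODONS:
                    continue
                if str(Seq(codon).translate()) != str(Seq(edited).translate()):
                    candidates.append((g, 3 * ci + cp))
    rng.shuffle(candidates)
    placed = 0
    for g, cpos in candidates:
        if placed >= recipe.recoding_sites:
            break
        gpos = g.coding_to_genome(cpos)
        if gpos in used:
            continue
        events.append(
            PlantedEvent(chrom, gpos, g.strand, _lrange(recipe.recoding_level_range), "recoding")
        )
        used.add(gpos)
        placed += 1
    if placed < recipe.recoding_sites:
        raise RecipeError("could not place all requested recoding sites")

    # --- clusters and hyper regions, preferring repeat-derived transcripts
    rep_units = [u for u in sim.noncoding_tx] or list(sim.transcription_units)
    if not rep_units and (recipe.clusters.count or recipe.hyper.count):
        raise RecipeError("no transcription units available for clusters")

    def _place_region(length: int) -> Interval | None:
        for _ in range(200):
            u = rep_units[int(rng.integers(0, len(rep_units)))]
            if len(u) < length + 20:
                continue
            start = int(rng.integers(u.start + 10, u.end - length - 10))
            iv = Interval(chrom, start, start + length, u.strand)
            if any(p in used for p in range(iv.start, iv.end)):
                continue
            return iv
        return None

    n_ok, attempts = 0, 0
    while n_ok < recipe.clusters.count:
        attempts += 1
        if attempts > 50 * max(1, recipe.clusters.count):
            raise RecipeError("could not place all requested clusters")
        iv = _place_region(recipe.clusters.span + 10)
        if iv is None:
            raise RecipeError("could not place all requested clusters")
        a_pos = _strand_base_positions(arr, iv, A)
        members: list[int] = []
        cur = iv.start
        for _k in range(recipe.clusters.sites_per_cluster):
            nxt = a_pos[a_pos >= cur + 8] if members else a_pos
            if len(nxt) == 0:
                break
            members.append(int(nxt[0]))
            cur = members[-1]
        if (
            len(members) < recipe.clusters.sites_per_cluster
            or members[-1] - members[0] > recipe.clusters.span
        ):
            continue
        regions.append(
            CorrelatedRegion(
                chrom,
                members[0],
                members[-1] + 1,
                iv.strand,
                recipe.clusters.level,
                1.0,
                np.asarray(members),
                "cluster",
            )
        )
        used.update(members)
        n_ok += 1

    for _ in range(recipe.hyper.count):
        iv = _place_region(recipe.hyper.region_length)
        if iv is None:
            raise RecipeError("could not place all requested hyper regions")
        members = _strand_base_positions(arr, iv, A)
        members = np.asarray([p for p in members if p not in used])
        if len(members) < 5:
            continue
        regions.append(
            CorrelatedRegion(
                chrom,
                iv.start,
                iv.end,
                iv.strand,
                recipe.hyper.level,
                recipe.hyper.per_read_fraction,
                members,
                "hyper",
            )
        )
        used.update(int(p) for p in members)

    # --- isolated sites, split between repeat transcripts and gene exons
    n_rep = int(round(recipe.isolated_sites * recipe.isolated_repeat_fraction))
    n_gen = recipe.isolated_sites - n_rep

    def _locus_weight(p: int) -> float:
        for r in sim.repeats:
            if r.interval.start <= p < r.interval.end:
                return float(np.exp(-recipe.repeat_divergence_decay * r.divergence))
        return 0.3  # flanking, non-repeat part of the transcript

    if n_rep and sim.noncoding_tx:
        pool, u5s, wts = [], [], []
        for u in sim.noncoding_tx:
            p = _strand_base_positions(arr, u, A)
            p = p[~np.isin(p, list(used))] if used else p
            if len(p) == 0:
                continue
            pool.append(p)
            u5s.append(_u5_mask(arr, p, u.strand))
            wts.append(np.asarray([_locus_weight(int(x)) for x in p]))
        pos = np.concatenate(pool)
        uniq, first = np.unique(pos, return_index=True)
        u5 = np.concatenate(u5s)[first]
        w = np.concatenate(wts)[first]
        strand_of = {}
        for u in sim.noncoding_tx:
            for p in range(u.start, u.end):
                strand_of.setdefault(p, u.strand)
        chosen = _biased_pick(rng, uniq, u5, min(n_rep, len(uniq)), recipe.motif_u_bias, w)
        for p in chosen:
            events.append(
                PlantedEvent(
                    chrom, int(p), strand_of[int(p)], _lrange(recipe.isolated_level_range), "isolated"
                )
            )
            used.add(int(p))
    if n_gen:
        pool, u5s, strands = [], [], []
        for g in sim.genes:
            for e in g.exons:
                iv = Interval(chrom, e.start, e.end, g.strand)
                p = _strand_base_positions(arr, iv, A)
                p = np.asarray([x for x in p if x not in used], dtype=np.int64)
                if len(p) == 0:
                    continue
                pool.append(p)
                u5s.append(_u5_mask(arr, p, g.strand))
                strands.extend([g.strand] * len(p))
        pos = np.concatenate(pool)
        u5 = np.concatenate(u5s)
        strands = np.asarray(strands)
        keep = np.full(len(pos), True)
        # avoid double-planting at antisense overlaps (same position, two strands)
        _, first = np.unique(pos, return_index=True)
        keep = np.zeros(len(pos), bool)
        keep[first] = True
        chosen_idx = rng.choice(
            np.flatnonzero(keep),
            size=min(n_gen, int(keep.sum())),
            replace=False,
            p=_bias_probs(u5[keep], recipe.motif_u_bias),
        )
        for i in np.sort(chosen_idx):
            events.append(
                PlantedEvent(
                    chrom, int(pos[i]), str(strands[i]), _lrange(recipe.isolated_level_range), "isolated"
                )
            )
            used.add(int(pos[i]))

    # --- genetic variants, away from every planted edit
    free = np.setdiff1d(np.arange(len(arr)), np.asarray(sorted(used), dtype=np.int64))
    picked = rng.choice(free, size=recipe.het_snps + recipe.hom_diffs, replace=False)
    het = np.sort(picked[: recipe.het_snps])
    hom = np.sort(picked[recipe.het_snps :])

    def _alt(p: int) -> str:
        ref = arr[p]
        return _seq.BASES[(int(ref) + int(rng.integers(1, 4))) % 4]

    het_snps = [(chrom, int(p), _seq.BASES[arr[p]], _alt(int(p))) for p in het]
    hom_diffs = [(chrom, int(p), _seq.BASES[arr[p]], _alt(int(p))) for p in hom]
    return Truth(events, regions, het_snps, hom_diffs)


def _bias_probs(u5: np.ndarray, bias: float) -> np.ndarray:
    w = np.where(u5, bias / 0.25, (1.0 - bias) / 0.75)
    return w / w.sum()


# ------------------------------------------------------------------ reads


@dataclass
class SampleReads:
    sample_id: str
    dna_pairs: list[tuple[AlignedRead, AlignedRead]]
    rna_pairs: list[tuple[AlignedRead, AlignedRead]]
    read_tags: dict[str, str]  # read id -> planted category side channel


def _haplotypes(sim: SimGenome, truth: Truth) -> tuple[np.ndarray, np.ndarray]:
    arr = sim.genome[sim.chrom]
    hap1 = arr.copy()
    for _, p, _, alt in truth.hom_diffs:
        hap1[p] = _seq.BASES.index(alt)
    hap2 = hap1.copy()
    for _, p, _, alt in truth.het_snps:
        hap2[p] = _seq.BASES.index(alt)
    return hap1, hap2


def _apply_errors(
    rng: np.random.Generator, codes: np.ndarray, recipe: SimulationRecipe
) -> tuple[np.ndarray, np.ndarray]:
    quals = np.full(len(codes), 40, dtype=np.int16)
    lowq = rng.random(len(codes)) < recipe.lowq_fraction
    quals[lowq] = 15
    err = rng.random(len(codes)) < np.where(lowq, 0.1, recipe.error_rate)
    err &= codes < 4
    if err.any():
        codes = codes.copy()
        codes[err] = (codes[err] + rng.integers(1, 4, int(err.sum()))) % 4
    return codes, quals


def simulate_reads(
    sim: SimGenome,
    truth: Truth,
    recipe: SimulationRecipe,
    sample_index: int,
) -> SampleReads:
    """Draw one sample's matched DNA and strand-specific RNA read pairs.

    Each RNA molecule carries each covered planted edit independently at
    its nominal level, except molecules drawn as editing molecules of a
    correlated region (cluster / hyper), which co-edit the region's
    member sites.  DNA is drawn from both haplotypes at 50:50.
    """
    rng = np.random.default_rng([recipe.seed, 101 + sample_index])
    sample_id = f"s{sample_index + 1}"
    chrom = sim.chrom
    L = recipe.read_length
    hap1, hap2 = _haplotypes(sim, truth)
    haps = (hap1, hap2)
    glen = len(hap1)

    # sorted point events for fast range queries
    ev_pos = np.asarray([e.pos for e in truth.events], dtype=np.int64)
    order = np.argsort(ev_pos, kind="stable")
    ev_pos = ev_pos[order]
    ev_list = [truth.events[i] for i in order]

    def _fragment(frag_min: int) -> tuple[int, int]:
        ln = int(np.clip(rng.normal(recipe.fragment_mean, recipe.fragment_sd), frag_min, None))
        return ln, 0

    dna_pairs = []
    n_dna = int(round(glen * recipe.dna_depth / (2 * L)))
    serial = 0
    for _ in range(n_dna):
        ln, _ = _fragment(2 * L)
        s = int(rng.integers(0, max(1, glen - ln)))
        e = s + ln
        frag = haps[int(rng.integers(0, 2))][s:e]
        rid = f"{sample_id}.d{serial:07d}"
        serial += 1
        flip = rng.random() < 0.5
        c1, q1 = _apply_errors(rng, frag[:L].copy(), recipe)
        c2, q2 = _apply_errors(rng, frag[-L:].copy(), recipe)
        if not flip:
            r1 = AlignedRead(rid, 1, chrom, s, "+", 60, c1, q1)
            r2 = AlignedRead(rid, 2, chrom, e - L, "-", 60, c2, q2)
        else:
            r1 = AlignedRead(rid, 1, chrom, e - L, "-", 60, c2, q2)
            r2 = AlignedRead(rid, 2, chrom, s, "+", 60, c1, q1)
        dna_pairs.append((r1, r2))

    rna_pairs = []
    tags: dict[str, str] = {}
    serial = 0
    for unit in sim.transcription_units:
        ulen = len(unit)
        if ulen < L + 10:
            continue
        n_frag = int(round(ulen * recipe.rna_depth / (2 * L)))
        regs = [
            r
            for r in truth.regions
            if r.strand == unit.strand and r.start < unit.end and r.end > unit.start
        ]
        for _ in range(n_frag):
            ln = int(
                np.clip(rng.normal(recipe.fragment_mean, recipe.fragment_sd), L, ulen)
            )
            s = unit.start + int(rng.integers(0, ulen - ln + 1))
            e = s + ln
            frag = haps[int(rng.integers(0, 2))][s:e].copy()
            tag = None
            for r in regs:
                if r.start >= e or r.end <= s:
                    continue
                if rng.random() >= r.level:
                    continue
                tag = "hyper"
                if r.category == "cluster":
                    mem = r.members[(r.members >= s) & (r.members < e)]
                    _edit(frag, mem - s, unit.strand)
                else:
                    want = A if unit.strand == "+" else T
                    cand = np.flatnonzero(frag == want)
                    cand = cand[(cand + s >= r.start) & (cand + s < r.end)]
                    hit = cand[rng.random(len(cand)) < r.per_site_prob]
                    _edit(frag, hit, unit.strand)
            lo = np.searchsorted(ev_pos, s)
            hi = np.searchsorted(ev_pos, e)
            for i in range(lo, hi):
                ev = ev_list[i]
                if ev.strand == unit.strand and rng.random() < ev.level:
                    _edit(frag, np.asarray([ev.pos - s]), unit.strand)
            rid = f"{sample_id}.r{serial:07d}"
            serial += 1
            if tag:
                tags[rid] = tag
            # dUTP: mate 2 reads the transcript 5' end on the original strand
            left, right = frag[:L].copy(), frag[-L:].copy()
            cl, ql = _apply_errors(rng, left, recipe)
            cr, qr = _apply_errors(rng, right, recipe)
            if unit.strand == "+":
                r2 = AlignedRead(rid, 2, chrom, s, "+", 60, cl, ql)
                r1 = AlignedRead(rid, 1, chrom, e - L, "-", 60, cr, qr)
            else:
                r2 = AlignedRead(rid, 2, chrom, e - L, "-", 60, cr, qr)
                r1 = AlignedRead(rid, 1, chrom, s, "+", 60, cl, ql)
            rna_pairs.append((r1, r2))
    return SampleReads(sample_id, dna_pairs, rna_pairs, tags)


def _edit(frag: np.ndarray, offsets: np.ndarray, strand: str) -> None:
    """Apply A-to-G edits (reference T-to-C for minus-strand transcripts)."""
    if strand == "+":
        sel = offsets[frag[offsets] == A]
        frag[sel] = G
    else:
        sel = offsets[frag[offsets] == T]
        frag[sel] = C


# ------------------------------------------------------------------ FASTQ helpers


def read_to_fastq(read: AlignedRead) -> tuple[str, str, np.ndarray]:
    """Sequenced-orientation (name, sequence, qualities) for a truth read."""
    if read.strand == "-":
        return read.read_id, _seq.decode(_seq.revcomp_codes(read.codes)), read.quals[::-1]
    return read.read_id, _seq.decode(read.codes), read.quals


# ------------------------------------------------------------------ bundle


def write_bundle(recipe: SimulationRecipe, outdir: str) -> dict:
    """Simulate a full dataset and write it as a plain-text file bundle.

    Returns a manifest dict with every written path plus the in-memory
    truth objects (under keys ``sim``, ``truth``).
    """
    io.ensure_dir(outdir)
    sim = simulate_genome(recipe)
    truth = plant_truth(sim, recipe)
    j = lambda name: f"{outdir}/{name}"
    recipe.to_yaml(j("recipe.yaml"))
    io.write_genome(sim.genome, j("genome.fa"))
    io.write_repeats_bed(sim.repeats, j("repeats.bed"))
    io.write_genes_gff3(sim.genes, j("genes.gff3"))
    truth.site_frame().to_csv(j("truth_sites.tsv"), sep="\t", index=False)
    truth.snp_frame().to_csv(j("truth_snps.tsv"), sep="\t", index=False)
    pd.DataFrame(sim.antisense_gene_pairs, columns=["gene_plus", "gene_minus"]).to_csv(
        j("truth_antisense_pairs.tsv"), sep="\t", index=False
    )
    manifest = {"samples": [], "sim": sim, "truth": truth, "recipe": recipe, "dir": outdir}
    for i in range(recipe.n_samples):
        reads = simulate_reads(sim, truth, recipe, i)
        sid = reads.sample_id
        for kind, pairs in (("dna", reads.dna_pairs), ("rna", reads.rna_pairs)):
            io.write_fastq(
                (read_to_fastq(r1) for r1, _ in pairs), j(f"{sid}.{kind}.R1.fastq")
            )
            io.write_fastq(
                (read_to_fastq(r2) for _, r2 in pairs), j(f"{sid}.{kind}.R2.fastq")
            )
            io.write_sam(pairs, sim.genome, j(f"{sid}.{kind}.truth.sam"))
        with open(j(f"{sid}.read_tags.tsv"), "w") as fh:
            fh.write("read_id\tcategory\n")
            for rid in sorted(reads.read_tags):
                fh.write(f"{rid}\t{reads.read_tags[rid]}\n")
        manifest["samples"].append(sid)
    return manifest
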