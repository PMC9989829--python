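"""Recoding sites: codon mapping, filter cascade, shared events, enrichment."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from editome import _seq
from editome.merge import build_editome
from editome.recoding import (
    RecodingSite,
    filter_recoding,
    go_enrichment,
    has_other_type_nearby,
    in_hyper_region,
    map_sites_to_codons,
    recurrence_stats,
    shared_events,
)
from editome.types import EditingSite, GeneModel, GenomeSeq, Interval


def _gene(chrom, strand, cds_seq, start=100):
    """Single-exon gene whose CDS holds ``cds_seq`` on the coding strand."""
    g = GeneModel("g1", chrom, strand)
    n = len(cds_seq)
    g.cds = [Interval(chrom, start, start + n, strand)]
    g.exons = [Interval(chrom, start, start + n, strand)]
    return g


def _genome_with_cds(cds_seq, strand, start=100, length=400):
    arr = np.full(length, _seq.C, dtype=np.uint8)
    seq = cds_seq if strand == "+" else _seq.revcomp(cds_seq)
    arr[start : start + len(seq)] = _seq.encode(seq)
    return GenomeSeq({"c": arr})


def _sites_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "type"])


class TestCodonMapping:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_gat_to_ggt_asp_to_gly(self, strand):
        cds = "ATGGATTAA"  # Met-Asp-stop
        genome = _genome_with_cds(cds, strand)
        gene = _gene("c", strand, cds)
        # the codon-2 A of GAT (coding position 4)
        gpos = gene.coding_to_genome(4)
        out = map_sites_to_codons(
            _sites_df([("c", gpos, strand, "A-to-G")]), [gene], genome
        )
        assert len(out) == 1
        s = out[0]
        assert (s.ref_codon, s.edited_codon) == ("GAT", "GGT")
        assert (s.ref_aa, s.edited_aa) == ("D", "G")
        assert (s.codon_index, s.codon_position) == (1, 2)
        assert s.nonsynonymous

    def test_aaa_to_gaa_lys_to_glu(self):
        cds = "ATGAAATAA"
        genome = _genome_with_cds(cds, "+")
        gene = _gene("c", "+", cds)
        gpos = gene.coding_to_genome(3)  # codon-1 position of AAA
        s = map_sites_to_codons(
            _sites_df([("c", gpos, "+", "A-to-G")]), [gene], genome
        )[0]
        assert (s.ref_codon, s.edited_codon, s.ref_aa, s.edited_aa) == (
            "AAA", "GAA", "K", "E"
        )
        assert s.codon_position == 1

    def test_gca_third_position_synonymous(self):
        cds = "ATGGCATAA"
        genome = _genome_with_cds(cds, "+")
        gene = _gene("c", "+", cds)
        gpos = gene.coding_to_genome(5)
        s = map_sites_to_codons(
            _sites_df([("c", gpos, "+", "A-to-G")]), [gene], genome
        )[0]
        assert (s.edited_codon, s.nonsynonymous) == ("GCG", False)

    def test_opposite_strand_site_not_recoding(self):
        cds = "ATGAAATAA"
        genome = _genome_with_cds(cds, "+")
        gene = _gene("c", "+", cds)
        gpos = gene.coding_to_genome(3)
        out = map_sites_to_codons(
            _sites_df([("c", gpos, "-", "A-to-G")]), [gene], genome
        )
        assert out == []

    def test_bad_cds_length_gene_skipped(self):
        genome = _genome_with_cds("ATGAAATAA", "+")
        gene = _gene("c", "+", "ATGAAATAA")
        gene.cds = [Interval("c", 100, 104, "+")]  # length 4
        out = map_sites_to_codons(_sites_df([("c", 101, "+", "A-to-G")]), [gene], genome)
        assert out == []

    def test_all_codons_against_genetic_code(self):
        from Bio.Seq import Seq

        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            for cp, b in enumerate(codon):
                if b != "A":
                    continue
                edited = codon[:cp] + "G" + codon[cp + 1 :]
                cds = "ATG" + codon + "TAA"
                if codon in ("TAA", "TAG", "TGA") or edited in ("TAA", "TAG", "TGA"):
                    continue
                genome = _genome_with_cds(cds, "+")
                gene = _gene("c", "+", cds)
                s = map_sites_to_codons(
                    _sites_df([("c", gene.coding_to_genome(3 + cp), "+", "A-to-G")]),
                    [gene], genome,
                )[0]
                assert s.ref_aa == str(Seq(codon).translate())
                assert s.edited_aa == str(Seq(edited).translate())
                assert s.nonsynonymous == (s.ref_aa != s.edited_aa)


def _editome_from(spec):
    """spec: list of (pos, type, samples: {sid: (edited, total)}), strand '+'."""
    per_sample: dict[str, list[EditingSite]] = {}
    for pos, subst, samples in spec:
        ref, alt = subst.split("-to-")
        for sid, (k, n) in samples.items():
            per_sample.setdefault(sid, []).append(
                EditingSite("c", pos, "+", ref, alt, 30, k, n, sid, "standard")
            )
    return build_editome(per_sample)


class TestFilters:
    def test_hyper_region_boundary_ten_vs_eleven(self):
        # run of 11 same-type sites, gaps <= 20 -> discarded
        run11 = [(100 + 15 * i, "A-to-G", {"s1": (4, 20), "s2": (4, 20)}) for i in range(11)]
        ed11 = _editome_from(run11)
        assert in_hyper_region("c", 100, "A-to-G", ed11.sites)
        # run of exactly 10 is allowed
        ed10 = _editome_from(run11[:10])
        assert not in_hyper_region("c", 100, "A-to-G", ed10.sites)
        # a 21-nt gap splits the run
        split = run11[:6] + [(100 + 15 * 5 + 21 + 15 * i, "A-to-G",
                              {"s1": (4, 20)}) for i in range(6)]
        eds = _editome_from(split)
        assert not in_hyper_region("c", 100, "A-to-G", eds.sites)

    def test_mixed_type_window_boundary(self):
        ed = _editome_from([
            (100, "A-to-G", {"s1": (4, 20), "s2": (4, 20)}),
            (108, "C-to-T", {"s1": (3, 20)}),
        ])
        assert has_other_type_nearby("c", 100, "A-to-G", ed.sites)
        ed_far = _editome_from([
            (100, "A-to-G", {"s1": (4, 20), "s2": (4, 20)}),
            (113, "C-to-T", {"s1": (3, 20)}),
        ])
        assert not has_other_type_nearby("c", 100, "A-to-G", ed_far.sites)

    def test_recurrence_thresholds(self):
        ed = _editome_from([(100, "A-to-G", {"s1": (2, 6), "s2": (1, 6)})])
        n, depth, level = recurrence_stats("c", 100, "+", ed)
        assert (n, depth) == (2, 12)
        assert level == pytest.approx((2 / 6 + 1 / 6) / 2)

    def _toy(self, rng, n=30):
        """A 30-site toy editome with known filter outcomes."""
        spec = []
        pos = 100
        for i in range(n):
            samples = {"s1": (4, 20)}
            if i % 3 != 0:
                samples["s2"] = (4, 20)
            spec.append((pos, "A-to-G", samples))
            pos += int(rng.integers(40, 120))
        # a dense 12-site same-type run swallowing site index 5
        base = spec[5][0]
        for j in range(1, 12):
            spec.append((base + 18 * j, "A-to-G", {"s1": (4, 20), "s2": (4, 20)}))
        # an other-type neighbor next to site index 7
        spec.append((spec[7][0] + 9, "C-to-T", {"s1": (4, 20)}))
        return spec

    def _oracle(self, spec, candidates):
        """Exhaustive reimplementation of the three filters."""
        rows = []
        for pos, subst, samples in spec:
            for sid, (k, n) in samples.items():
                rows.append((pos, subst, sid, k, n))
        ag = sorted({p for p, t, *_ in rows if t == "A-to-G"})
        keep = []
        for c in candidates:
            # hyper region: grow the run around c
            run = [p for p in ag if p == c.pos]
            assert run
            i = ag.index(c.pos)
            lo = hi = i
            while lo > 0 and ag[lo] - ag[lo - 1] <= 20:
                lo -= 1
            while hi < len(ag) - 1 and ag[hi + 1] - ag[hi] <= 20:
                hi += 1
            if hi - lo + 1 > 10:
                continue
            if any(t != "A-to-G" and abs(p - c.pos) <= 12 for p, t, *_ in rows):
                continue
            obs = [(sid, k, n) for p, t, sid, k, n in rows if p == c.pos and t == "A-to-G"]
            n_samples = len({sid for sid, _, _ in obs})
            depth = sum(n for _, _, n in obs)
            level = np.mean([k / n for _, k, n in obs])
            if n_samples >= 2 and depth >= 10 and level >= 0.1:
                keep.append(c.pos)
        return sorted(keep)

    def test_cascade_matches_enumeration_oracle(self, rng):
        spec = self._toy(rng)
        ed = _editome_from(spec)
        cands = [
            RecodingSite("c", p, "+", "g", 0, 1, "AAA", "GAA", "K", "E", True)
            for p, t, _ in spec if t == "A-to-G"
        ]
        got = sorted(s.pos for s in filter_recoding(cands, ed))
        want = self._oracle(spec, cands)
        assert got == want
        assert got  # the oracle keeps something

    def test_filters_order_independent(self, rng):
        """Each filter is a pure predicate of (site, editome): applying them
        in any order yields the same retained set."""
        spec = self._toy(rng)
        ed = _editome_from(spec)
        sites = ed.sites
        cands = [
            RecodingSite("c", p, "+", "g", 0, 1, "AAA", "GAA", "K", "E", True)
            for p, t, _ in spec if t == "A-to-G"
        ]

        def predicates(c):
            f1 = not in_hyper_region(c.chrom, c.pos, "A-to-G", sites)
            f2 = not has_other_type_nearby(c.chrom, c.pos, "A-to-G", sites)
            n, d, l = recurrence_stats(c.chrom, c.pos, c.strand, ed)
            f3 = n >= 2 and d >= 10 and l >= 0.1
            return [f1, f2, f3]

        cascade = {s.pos for s in filter_recoding(cands, ed)}
        for order in itertools.permutations(range(3)):
            kept = {c.pos for c in cands if all(np.array(predicates(c))[list(order)])}
            assert kept == cascade


class TestSharedEvents:
    def _site(self, gene, ci, aa0, aa1, level=0.3, n_samples=2):
        return RecodingSite("c", 0, "+", gene, ci, 1, "AAA", "GAA", aa0, aa1,
                            True, n_samples, 20, level)

    def test_same_column_same_change_shared(self):
        msa = {"sp1|gA": "MK-LV", "sp2|gB": "MKQLV"}
        per = {"sp1": [self._site("gA", 1, "K", "E")],
               "sp2": [self._site("gB", 1, "K", "E")]}
        out = shared_events(per, msa)
        assert len(out) == 1
        ev = out[0]
        assert ev.species == ("sp1", "sp2") and ev.column == 1

    def test_gapped_columns_aligned(self):
        # sp1 position 2 (L) is column 3 because of its gap
        msa = {"sp1|gA": "MK-LV", "sp2|gB": "MKQLV"}
        per = {"sp1": [self._site("gA", 2, "L", "P")],
               "sp2": [self._site("gB", 3, "L", "P")]}
        assert len(shared_events(per, msa)) == 1

    def test_different_change_not_shared(self):
        msa = {"sp1|gA": "MKLV", "sp2|gB": "MKLV"}
        per = {"sp1": [self._site("gA", 1, "K", "E")],
               "sp2": [self._site("gB", 1, "K", "R")]}
        assert shared_events(per, msa) == []

    def test_sibling_pair_removed(self):
        msa = {"dmel|gA": "MKLV", "dsim|gB": "MKLV", "dvir|gC": "MKLV"}
        per = {"dmel": [self._site("gA", 1, "K", "E")],
               "dsim": [self._site("gB", 1, "K", "E")]}
        assert shared_events(per, msa, sibling_pair=("dmel", "dsim")) == []
        per["dvir"] = [self._site("gC", 1, "K", "E")]
        out = shared_events(per, msa, sibling_pair=("dmel", "dsim"))
        assert len(out) == 1 and len(out[0].species) == 3

    def test_eligibility_level_or_samples(self):
        msa = {"sp1|gA": "MKLV", "sp2|gB": "MKLV"}
        weak = self._site("gA", 1, "K", "E", level=0.05, n_samples=1)
        strong = self._site("gB", 1, "K", "E")
        assert shared_events({"sp1": [weak], "sp2": [strong]}, msa) == []

    def test_missing_protein_skipped(self):
        msa = {"sp2|gB": "MKLV"}
        per = {"sp1": [self._site("gA", 1, "K", "E")],
               "sp2": [self._site("gB", 1, "K", "E")]}
        assert shared_events(per, msa) == []


def test_rpkm_uniform_coverage():
    """Uniform 10x exonic coverage: RPKM follows directly from the counts."""
    from editome.pileup import Pileup
    from editome.recoding import rpkm

    genome = GenomeSeq({"c": np.zeros(2000, dtype=np.uint8)})
    g = _gene("c", "+", "A" * 900, start=100)
    pile = Pileup(genome, stranded=True, min_baseq=30)
    pile.counts["c"][0, 0, 100:1000] = 10
    got = rpkm(g, {"s1": pile}, {"s1": 1000.0}, read_length=100)
    # 900 nt at 10x = 9000 bases = 90 reads; 90 / 0.9 kb / (1000/1e6 M reads)
    assert got["s1"] == pytest.approx(90 / 0.9 / (1000 / 1e6))


class TestEnrichment:
    def test_equal_proportions_p_one(self):
        terms = {f"g{i}": {"T"} for i in range(110)}
        recoded = {f"g{i}" for i in range(10)}
        background = {f"g{i}" for i in range(10, 110)}
        out = go_enrichment(recoded, background, terms)
        assert out.iloc[0].p_value == pytest.approx(1.0)

    def test_planted_enrichment_detected(self, rng):
        gene_terms = {}
        recoded, background = set(), set()
        for i in range(20):
            g = f"r{i}"
            recoded.add(g)
            gene_terms[g] = {"GO:target"} if i < 15 else {"GO:other"}
        for i in range(400):
            g = f"b{i}"
            background.add(g)
            gene_terms[g] = {"GO:target"} if i < 30 else {"GO:other"}
        out = go_enrichment(recoded, background, gene_terms)
        row = out[out["term"] == "GO:target"].iloc[0]
        assert row.significant and row.q_value < 1e-6

    def test_unannotated_term_skipped(self):
        out = go_enrichment({"a"}, {"b"}, {"a": set(), "b": set()})
        assert out.empty
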