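"""Landscape analyses: clusters, annotation, editability, divergence, dsRNA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from editome import _seq
from editome.landscape import (
    annotate_sites,
    divergence_bins,
    dsrna_forming_potential,
    editability,
    element_masks,
    find_clusters,
    sample_control_sites,
    transcribed_repeat_loci,
)
from editome.pileup import Pileup
from editome.types import GeneModel, GenomeSeq, Interval, RepeatLocus


def brute_force_clusters(positions, max_gap=30, min_size=3):
    """O(n^2) oracle: for every site, grow the maximal run containing it."""
    pos = sorted(set(positions))
    clustered = set()
    clusters = set()
    for i in range(len(pos)):
        lo = hi = i
        while lo > 0 and pos[lo] - pos[lo - 1] <= max_gap:
            lo -= 1
        while hi < len(pos) - 1 and pos[hi + 1] - pos[hi] <= max_gap:
            hi += 1
        if hi - lo + 1 >= min_size:
            clusters.add((pos[lo], pos[hi], hi - lo + 1))
            clustered.update(pos[lo : hi + 1])
    return clusters, clustered


class TestClusters:
    def test_basic_cluster(self):
        clusters, frac = find_clusters({"c": np.array([100, 125, 150])})
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.size) == (100, 150, 3)
        assert frac == 1.0

    def test_gap_31_and_size_2_boundaries(self):
        clusters, frac = find_clusters({"c": np.array([100, 131])})
        assert clusters == [] and frac == 0.0
        clusters, _ = find_clusters({"c": np.array([100, 130, 160])})
        assert len(clusters) == 1  # gap exactly 30 joins

    def test_random_configurations_match_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 40))
            pos = np.sort(rng.choice(2000, size=n, replace=False))
            clusters, frac = find_clusters({"c": pos})
            want_clusters, want_sites = brute_force_clusters(pos)
            got = {(c.start, c.end, c.size) for c in clusters}
            assert got == want_clusters
            got_sites = {p for c in clusters for p in c.members}
            assert got_sites == want_sites
            assert frac == (len(want_sites) / len(set(pos.tolist())))

    def test_every_clustered_site_in_exactly_one_cluster(self, rng):
        pos = np.sort(rng.choice(500, 60, replace=False))
        clusters, _ = find_clusters({"c": pos})
        seen = [p for c in clusters for p in c.members]
        assert len(seen) == len(set(seen))


class TestAnnotation:
    @pytest.fixture()
    def setup(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 3000, dtype=np.uint8)})
        repeats = [RepeatLocus(Interval("c", 100, 400, "."), "SINE", 0.1)]
        g = GeneModel("g1", "c", "+")
        g.utr5 = [Interval("c", 200, 300, "+")]
        g.cds = [Interval("c", 300, 600, "+"), Interval("c", 700, 1000, "+")]
        g.introns = [Interval("c", 600, 700, "+")]
        g.utr3 = [Interval("c", 1000, 1100, "+")]
        g.exons = [Interval("c", 200, 600, "+"), Interval("c", 700, 1100, "+")]
        masks = element_masks(genome, repeats, [g])
        return genome, repeats, [g], masks

    def test_multi_and_single_labels(self, setup):
        _, _, _, masks = setup
        sites = pd.DataFrame({
            "chrom": ["c"] * 4, "pos": [350, 2500, 650, 250], "strand": ["+"] * 4,
        })
        out = annotate_sites(sites, masks)
        assert out.loc[0, "labels"] == "CDS,SINE"
        assert out.loc[0, "single_label"] == "repeat"
        assert out.loc[1, "labels"] == "intergenic"
        assert out.loc[2, "single_label"] == "intron"
        assert out.loc[3, "labels"] == "5UTR,SINE"

    def test_label_counts_match_nested_loop_oracle(self, setup, rng):
        genome, repeats, genes, masks = setup
        pos = rng.integers(0, 3000, 100)
        sites = pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+"})
        out = annotate_sites(sites, masks)
        ivs = []
        for r in repeats:
            ivs.append((r.repeat_class, r.interval))
        g = genes[0]
        for name, lst in (("5UTR", g.utr5), ("CDS", g.cds), ("intron", g.introns),
                          ("3UTR", g.utr3)):
            for iv in lst:
                ivs.append((name, iv))
        for row in out.itertuples(index=False):
            want = sorted({name for name, iv in ivs if iv.start <= row.pos < iv.end})
            assert row.labels == ",".join(want or ["intergenic"])


def _stranded_uniform(genome, depth, lo=0, hi=None):
    pile = Pileup(genome, stranded=True, min_baseq=30)
    hi = hi if hi is not None else genome.length("c")
    for chrom in genome:
        pile.counts[chrom][:, 0, lo:hi] = depth  # depth carried on base A rows
    return pile


class TestControls:
    def test_depth_matching_rule(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 4000, dtype=np.uint8)})
        pile = Pileup(genome, stranded=True, min_baseq=30)
        # strand + depth: 50 in the left half, 10 in the right half
        pile.counts["c"][0, 0, :2000] = 50
        pile.counts["c"][0, 0, 2000:] = 10
        a_left = np.flatnonzero(genome["c"][:2000] == _seq.A)
        sites = pd.DataFrame({"chrom": "c", "pos": a_left[:20], "strand": "+"})
        ctrl = sample_control_sites(sites, pile, genome, seed=0)
        assert len(ctrl) <= len(sites)
        assert (ctrl["depth"] >= 40).all() and (ctrl["depth"] <= 60).all()
        assert not set(ctrl["pos"]) & set(sites["pos"])
        assert ctrl["pos"].is_unique


class TestEditability:
    def test_hand_computed_fixture(self, rng):
        genome = GenomeSeq({"c": np.zeros(3000, dtype=np.uint8)})  # all A
        masks = element_masks(genome, [], [])
        masks["c"]["CDS"] = np.zeros(3000, bool)
        masks["c"]["CDS"][:1000] = True
        pile = _stranded_uniform(genome, 5, 0, 3000)
        sites = pd.DataFrame({
            "chrom": ["c"] * 4, "pos": [10, 20, 30, 1500], "strand": ["+"] * 4,
            "rna_total": [20, 20, 5, 20], "level": [0.1, 0.5, 0.2, 0.3],
        })
        out = editability(sites, pile, genome, masks, ["CDS"])
        row = out.iloc[0]
        # 3 sites over 1000 transcribed A (plus strand only; minus strand of
        # an all-A genome has no A)
        assert row.n_transcribed_adenosines == 1000
        assert row.density_per_million == pytest.approx(3 / 1000 * 1e6)

    def test_weighted_counts_levels_and_depth_floor(self, rng):
        genome = GenomeSeq({"c": np.zeros(2000, dtype=np.uint8)})
        masks = element_masks(genome, [], [])
        masks["c"]["CDS"] = np.ones(2000, bool)
        pile = _stranded_uniform(genome, 12, 0, 2000)
        sites = pd.DataFrame({
            "chrom": ["c"] * 3, "pos": [10, 20, 30], "strand": ["+"] * 3,
            "rna_total": [20, 20, 5], "level": [0.1, 0.5, 0.9],
        })
        out = editability(sites, pile, genome, masks, ["CDS"], weighted=True)
        row = out.iloc[0]
        # the depth-5 site is excluded; 0.1 + 0.5 = 0.6 sites over 2000 A
        assert row.n_sites == pytest.approx(0.6)
        assert row.density_per_million == pytest.approx(0.6 / 2000 * 1e6)

    def test_zero_adenosine_class_is_missing(self, rng):
        genome = GenomeSeq({"c": np.full(100, 1, dtype=np.uint8)})  # all C
        masks = element_masks(genome, [], [])
        masks["c"]["CDS"] = np.ones(100, bool)
        pile = _stranded_uniform(genome, 5)
        out = editability(pd.DataFrame(columns=["chrom", "pos", "strand",
                                                "rna_total", "level"]),
                          pile, genome, masks, ["CDS"])
        assert np.isnan(out.iloc[0].density_per_million)


class TestDivergenceBins:
    def _setup(self, rng, n_loci=40):
        genome = GenomeSeq({"c": rng.integers(0, 4, n_loci * 150, dtype=np.uint8)})
        repeats = [
            RepeatLocus(Interval("c", i * 150, i * 150 + 100, "."), "SINE",
                        round(0.01 + 0.005 * i, 4))
            for i in range(n_loci)
        ]
        pile = _stranded_uniform(genome, 5)
        # decaying density: early (low-divergence) loci get sites
        sites = []
        for i in range(n_loci):
            n = max(0, 6 - i // 4)
            a = np.flatnonzero(genome["c"][i * 150 : i * 150 + 100] == _seq.A)
            for p in a[:n]:
                sites.append(("c", i * 150 + int(p), "+"))
        df = pd.DataFrame(sites, columns=["chrom", "pos", "strand"])
        return genome, repeats, pile, df

    def test_equal_bin_counts_and_negative_trend(self, rng):
        genome, repeats, pile, sites = self._setup(rng)
        out = divergence_bins(sites, repeats, pile, genome)
        assert out["n_loci"].tolist() == [4] * 10
        from editome.stats import spearman
        rho, _ = spearman(out["bin"], out["density_per_million"])
        assert rho < 0

    def test_too_few_loci_raises(self, rng):
        genome, repeats, pile, sites = self._setup(rng, n_loci=6)
        with pytest.raises(ValueError, match="bin count"):
            divergence_bins(sites, repeats, pile, genome)

    def test_untranscribed_loci_excluded(self, rng):
        genome, repeats, pile, _ = self._setup(rng)
        pile.counts["c"][:, :, : 5 * 150] = 0  # silence the first 5 loci
        loci = transcribed_repeat_loci(repeats, pile)
        assert len(loci) == len(repeats) - 5


class TestDsrnaPotential:
    def test_perfect_inverted_pairs_ratio_one(self, rng):
        unit = rng.integers(0, 4, 60, dtype=np.uint8)
        parts, repeats = [], []
        pos = 0
        for _ in range(6):
            parts += [unit, rng.integers(0, 4, 100, dtype=np.uint8),
                      _seq.revcomp_codes(unit),
                      rng.integers(0, 4, 200, dtype=np.uint8)]
            repeats.append(RepeatLocus(Interval("c", pos, pos + 60, "."), "SINE", 0.0))
            repeats.append(RepeatLocus(Interval("c", pos + 160, pos + 220, "."), "SINE", 0.0))
            pos += 420
        genome = GenomeSeq({"c": np.concatenate(parts)})
        out = dsrna_forming_potential(genome, repeats, n_sites=200, reps=2, seed=1)
        rep = out[out["class"] == "repeat"]["ratio"]
        assert (rep > 0.95).all()

    def test_random_genome_ratio_near_zero(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 20_000, dtype=np.uint8)})
        out = dsrna_forming_potential(genome, [], n_sites=300, reps=2, seed=1)
        nonrep = out[out["class"] == "non_repeat"]["ratio"]
        assert (nonrep <= 0.01).all()

    def test_seeded_bit_reproducible(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 5_000, dtype=np.uint8)})
        reps = [RepeatLocus(Interval("c", 100, 400, "."), "SINE", 0.0)]
        a = dsrna_forming_potential(genome, reps, n_sites=100, reps=3, seed=9)
        b = dsrna_forming_potential(genome, reps, n_sites=100, reps=3, seed=9)
        pd.testing.assert_frame_equal(a, b)
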