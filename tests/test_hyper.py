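"""Three-letter transform, prefilter, hyper scoring and type combination."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editome import _seq
from editome.hyper import (
    HyperCandidatePair,
    align_transformed,
    combine_twelve_types,
    prefilter_pair,
    score_hyper_read,
    transform_read,
    transform_reference,
)
from editome.types import AlignedRead, EditingSite, GenomeSeq


def _pair(codes1, codes2, rid="p0"):
    c1, c2 = np.asarray(codes1, np.uint8), np.asarray(codes2, np.uint8)
    return HyperCandidatePair(
        rid, c1, np.full(len(c1), 40, np.int16), c2, np.full(len(c2), 40, np.int16),
        "unaligned",
    )


class TestTransform:
    def test_mate1_t_to_c(self):
        got = transform_read(_seq.encode("ATTGC"), mate=1, subst="A-to-G")
        assert _seq.decode(got) == "ACCGC"

    def test_mate2_a_to_g(self):
        got = transform_read(_seq.encode("ATTGC"), mate=2, subst="A-to-G")
        assert _seq.decode(got) == "GTTGC"

    def test_positive_reference_a_to_g(self):
        g = GenomeSeq.from_strings({"c": "AATG"})
        pos, neg = transform_reference(g, "A-to-G")
        assert pos.string("c") == "GGTG"
        assert neg.string("c") == "AACG"

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60),
           st.sampled_from(["A-to-G", "C-to-T", "G-to-A", "T-to-C"]),
           st.sampled_from([1, 2]))
    @settings(deadline=None, derandomize=True)
    def test_transform_idempotent(self, s, subst, mate):
        codes = _seq.encode(s)
        once = transform_read(codes, mate, subst)
        assert np.array_equal(transform_read(once, mate, subst), once)

    def test_unknown_type_raises(self):
        with pytest.raises(ValueError):
            transform_read(_seq.encode("ACGT"), 2, "A-to-A")


class TestPrefilter:
    def test_n_fraction(self):
        ok = _seq.encode("ACGT" * 25)
        too_many_n = _seq.encode("N" * 11 + "ACGT" * 22 + "A")
        assert not prefilter_pair(_pair(too_many_n, ok))
        boundary = _seq.encode("N" * 10 + "ACGT" * 22 + "AC")  # exactly 10%
        assert prefilter_pair(_pair(boundary, ok))

    def test_single_base_composition(self):
        ok = _seq.encode("ACGT" * 25)
        skewed = _seq.encode("A" * 65 + "CGT" * 11 + "CG")  # 65% A
        assert not prefilter_pair(_pair(skewed, ok))
        balanced = _seq.encode("A" * 30 + "C" * 25 + "G" * 25 + "T" * 20)
        assert prefilter_pair(_pair(balanced, balanced))
        missing_base = _seq.encode("ACG" * 33 + "A")  # T at 0% < 10%
        assert not prefilter_pair(_pair(missing_base, ok))

    def test_either_mate_fails_pair(self):
        ok = _seq.encode("ACGT" * 25)
        bad = _seq.encode("A" * 70 + "CGT" * 10)
        assert not prefilter_pair(_pair(ok, bad))


class TestScoring:
    def _read(self, genome, start, n_total_mm, n_expected, rng):
        arr = genome["c"]
        codes = arr[start : start + 100].copy()
        # plant expected-type (A->G) mismatches on reference As in the
        # trimmed span, then other-type mismatches
        trimmed = np.arange(10, 90)
        a_pos = trimmed[arr[start + trimmed] == _seq.A]
        exp = a_pos[:n_expected]
        codes[exp] = _seq.G
        others = trimmed[~np.isin(trimmed, exp) & (arr[start + trimmed] != _seq.A)]
        oth = others[: n_total_mm - n_expected]
        codes[oth] = (codes[oth] + 2) % 4
        return AlignedRead("r", 2, "c", start, "+", 37, codes,
                           np.full(100, 40, np.int16))

    def test_verdict_thresholds(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 1000, dtype=np.uint8)})
        # 6 mismatches on 80 nt (7.5% > 5%), 5/6 expected (83% > 60%)
        ha = score_hyper_read(self._read(genome, 100, 6, 5, rng), genome, "A-to-G", "positive")
        assert ha.verdict and ha.mismatches == 6 and ha.expected_mismatches == 5
        # 3 mismatches: 3.75% <= 5%
        assert not score_hyper_read(self._read(genome, 100, 3, 3, rng), genome,
                                    "A-to-G", "positive").verdict
        # exactly 5% (4/80) fails the strict inequality
        assert not score_hyper_read(self._read(genome, 100, 4, 4, rng), genome,
                                    "A-to-G", "positive").verdict
        # all-match read
        assert not score_hyper_read(self._read(genome, 100, 0, 0, rng), genome,
                                    "A-to-G", "positive").verdict
        # 60% expected exactly fails: 10 mismatches, 6 expected
        ha = score_hyper_read(self._read(genome, 100, 10, 6, rng), genome,
                              "A-to-G", "positive")
        assert ha.expected_mismatches / ha.mismatches == pytest.approx(0.6)
        assert not ha.verdict

    def test_short_reads_discarded(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 200, dtype=np.uint8)})
        ok = AlignedRead("r", 1, "c", 0, "+", 37, genome["c"][:41],
                         np.full(41, 40, np.int16))
        assert score_hyper_read(ok, genome, "A-to-G", "positive") is not None
        tiny = AlignedRead("r", 1, "c", 0, "+", 37, genome["c"][:40],
                           np.full(40, 40, np.int16))
        assert score_hyper_read(tiny, genome, "A-to-G", "positive") is None


class TestAlignTransformed:
    def test_plus_transcript_hyper_pair_lands_on_positive_ref(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 3000, dtype=np.uint8)})
        arr = genome["c"]
        frag = arr[1000:1260].copy()
        a_idx = np.flatnonzero(frag == _seq.A)
        frag[a_idx[::2]] = _seq.G  # heavy A>G editing along the molecule
        # dUTP mate geometry for a plus-strand transcript
        m2 = frag[:100]
        m1 = _seq.revcomp_codes(frag[-100:])
        placed = align_transformed([_pair(m1, m2)], genome, "A-to-G")
        assert len(placed) == 1
        _, r1, r2, which = placed[0]
        assert which == "positive"
        assert (r2.start, r2.strand) == (1000, "+")
        assert (r1.start, r1.strand) == (1160, "-")
        # untransformed sequences restored in reference-forward orientation
        assert np.array_equal(r2.codes, frag[:100])

    def test_minus_transcript_lands_on_negative_ref(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 3000, dtype=np.uint8)})
        arr = genome["c"]
        frag = arr[1000:1260].copy()
        t_idx = np.flatnonzero(frag == _seq.T)
        frag[t_idx[::2]] = _seq.C  # A>G on the minus transcript = T>C forward
        m2 = _seq.revcomp_codes(frag[-100:])
        m1 = frag[:100]
        placed = align_transformed([_pair(m1, m2)], genome, "A-to-G")
        assert len(placed) == 1
        _, r1, r2, which = placed[0]
        assert which == "negative"
        assert (r2.strand, r1.strand) == ("-", "+")

    def test_wrong_orientation_discarded(self, rng):
        genome = GenomeSeq({"c": rng.integers(0, 4, 3000, dtype=np.uint8)})
        arr = genome["c"]
        frag = arr[500:760].copy()
        a_idx = np.flatnonzero(frag == _seq.A)
        frag[a_idx[::2]] = _seq.G
        # swap the mates: mate2 now reverse-complement on the positive ref
        m1 = frag[:100]
        m2 = _seq.revcomp_codes(frag[-100:])
        placed = align_transformed([_pair(m1, m2)], genome, "A-to-G")
        assert placed == []


class TestCombine:
    def _site(self, pos, subst, strand="+", edited=3):
        ref, alt = subst.split("-to-")
        return EditingSite("c", pos, strand, ref, alt, 30, edited, 10, "s1", "hyper")

    def test_single_type_kept_conflict_dropped(self):
        per_type = {
            "A-to-G": [self._site(10, "A-to-G"), self._site(50, "A-to-G")],
            "C-to-T": [self._site(50, "C-to-T", strand="-")],
        }
        out = combine_twelve_types(per_type)
        assert [s.pos for s in out] == [10]

    def test_duplicate_same_type_deduplicated(self):
        per_type = {
            "A-to-G": [self._site(10, "A-to-G", edited=3)],
            "C-to-T": [self._site(10, "A-to-G", edited=5)],
        }
        out = combine_twelve_types(per_type)
        assert len(out) == 1 and out[0].rna_edited == 5
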