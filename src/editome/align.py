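"""Ungapped seed-and-extend alignment.

Two aligners live here:

* :class:`UngappedAligner` — maps reads (and read pairs) to a genome by
  exact k-mer seeding plus full-length ungapped verification.  Used to
  align simulated strand-specific RNA reads and the three-letter
  transformed reads of the hyper-editing stage.  A read with at most
  ``floor(L/k) - 1`` mismatches always retains one exact seed, so the
  default (k=13, reads ~100 nt, mismatch cap 5) is fully sensitive.
  MAPQ is a uniqueness proxy: 37 for a unique best placement, 0 for ties.

* :func:`rc_local_align` — the reverse-complement local aligner behind
  the dsRNA-forming-potential estimate and the intramolecular-folding
  exclusion: seeds shared k-mers between the query and the reverse
  complement of the target, X-drop extends each seed without gaps, and
  reports the best alignment meeting identity/length/span thresholds.

N bases never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .types import GenomeSeq


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class PairHit:
    hit1: Hit
    hit2: Hit
    mapq1: int
    mapq2: int

    @property
    def total_mismatches(self) -> int:
        return self.hit1.mismatches + self.hit2.mismatches


class UngappedAligner:
    """Exact k-mer index over a genome with ungapped read placement."""

    def __init__(self, genome: GenomeSeq, k: int = 13):
        self.k = k
        self.chroms: list[str] = list(genome)
        parts, offsets = [], []
        off = 0
        spacer = np.full(k, 4, dtype=np.uint8)
        for name in self.chroms:
            offsets.append(off)
            codes = genome[name]
            parts.append(codes)
            off += len(codes) + k
            parts.append(spacer)
        self.seq = np.concatenate(parts)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray([genome.length(c) for c in self.chroms])
        kc = _seq.kmer_codes(self.seq, k)
        valid = np.flatnonzero(kc >= 0)
        order = np.argsort(kc[valid], kind="stable")
        self._sorted_codes = kc[valid][order]
        self._sorted_pos = valid[order]

    def _seed_positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted_codes, code, "left")
        hi = np.searchsorted(self._sorted_codes, code, "right")
        return self._sorted_pos[lo:hi]

    def _global_to_chrom(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.offsets, gpos, "right") - 1)
        return ci, gpos - int(self.offsets[ci])

    def hits(self, codes: np.ndarray, max_mm: int) -> list[Hit]:
        """All placements of the read (either strand) with <= max_mm mismatches."""
        out: list[Hit] = []
        L = len(codes)
        if L < self.k:
            return out
        for strand, q in (("+", codes), ("-", _seq.revcomp_codes(codes))):
            qk = _seq.kmer_codes(q, self.k)
            starts: set[int] = set()
            for off in range(0, L - self.k + 1, self.k):
                code = int(qk[off])
                if code < 0:
                    continue
                for gp in self._seed_positions(code):
                    starts.add(int(gp) - off)
            for gs in sorted(starts):
                ci, cpos = self._global_to_chrom(gs)
                if cpos < 0 or cpos + L > self.lengths[ci]:
                    continue
                mm = int(np.count_nonzero(self.seq[gs : gs + L] != q))
                # query N bases match nothing either
                if mm <= max_mm:
                    out.append(Hit(self.chroms[ci], cpos, strand, mm))
        return out

    def align(self, codes: np.ndarray, max_mm: int = 5) -> tuple[Hit | None, int]:
        """Best single-end placement and its MAPQ proxy (37 unique / 0 tied)."""
        hits = self.hits(codes, max_mm)
        if not hits:
            return None, 0
        hits.sort(key=lambda h: (h.mismatches, self.chroms.index(h.chrom), h.start, h.strand))
        best = hits[0]
        tied = len(hits) > 1 and hits[1].mismatches == best.mismatches
        return best, 0 if tied else 37

    def align_pair(
        self,
        codes1: np.ndarray,
        codes2: np.ndarray,
        max_mm: int = 5,
        max_insert: int = 1000,
        required_strand1: str | None = None,
        required_strand2: str | None = None,
    ) -> PairHit | None:
        """Best concordant (inward-facing, same-chromosome) pair placement.

        ``required_strand*`` restricts the mapping strand of each mate, as
        the hyper-editing stage demands per transformed reference.  Exact
        score ties between distinct placements yield MAPQ 0 on both mates.
        """
        h1 = self.hits(codes1, max_mm)
        h2 = self.hits(codes2, max_mm)
        if required_strand1 is not None:
            h1 = [h for h in h1 if h.strand == required_strand1]
        if required_strand2 is not None:
            h2 = [h for h in h2 if h.strand == required_strand2]
        pairs = []
        for a in h1:
            for b in h2:
                if a.chrom != b.chrom or a.strand == b.strand:
                    continue
                if a.strand == "+":
                    fwd, rev, rev_len = a, b, len(codes2)
                else:
                    fwd, rev, rev_len = b, a, len(codes1)
                if not (
                    fwd.start <= rev.start
                    and rev.start + rev_len - fwd.start <= max_insert
                ):
                    continue
                pairs.append((a.mismatches + b.mismatches, a, b))
        if not pairs:
            return None
        pairs.sort(key=lambda t: (t[0], t[1].start, t[2].start, t[1].strand))
        best = pairs[0]
        tied = len(pairs) > 1 and pairs[1][0] == best[0]
        mq = 0 if tied else 37
        return PairHit(best[1], best[2], mq, mq)


# ------------------------------------------------------------------ rc local


@dataclass(frozen=True)
class RCAlignment:
    """An ungapped local alignment of query vs reverse-complement(target).

    ``t_start``/``t_end`` are in original target coordinates.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return self.matches / self.length


def _xdrop_segment(match: np.ndarray, seed_start: int, seed_end: int, xdrop: int,
                   mismatch_penalty: int = 2) -> tuple[int, int, int]:
    """Extend [seed_start, seed_end) along a precomputed match vector.

    Returns (start, end, n_matches) of the maximal-score extension with
    match +1 / mismatch -``mismatch_penalty`` and X-drop termination.
    """
    # right extension
    best_r, score, best_score = seed_end, 0, 0
    i = seed_end
    n = len(match)
    while i < n:
        score += 1 if match[i] else -mismatch_penalty
        if score > best_score:
            best_score, best_r = score, i + 1
        if score < best_score - xdrop:
            break
        i += 1
    # left extension
    best_l, score, best_score = seed_start, 0, 0
    i = seed_start - 1
    while i >= 0:
        score += 1 if match[i] else -mismatch_penalty
        if score > best_score:
            best_score, best_l = score, i
        if score < best_score - xdrop:
            break
        i -= 1
    seg = match[best_l:best_r]
    return best_l, best_r, int(seg.sum())


def rc_local_align(
    query: np.ndarray | str,
    target: np.ndarray | str,
    min_identity: float = 0.8,
    min_len: int = 50,
    must_span: int | None = None,
    k: int = 13,
    xdrop: int = 20,
) -> RCAlignment | None:
    """Best reverse-complement ungapped local alignment, or None.

    Finds shared k-mers between ``query`` and the reverse complement of
    ``target``, X-drop extends every seed diagonal, and returns the
    highest-scoring (most matching bases) alignment with identity >=
    ``min_identity``, length >= ``min_len`` and, when ``must_span`` is
    given, covering that query position.  Ties break toward the leftmost
    original-target position, then leftmost query position.
    """
    q = _seq.encode(query) if isinstance(query, str) else np.asarray(query, np.uint8)
    t = _seq.encode(target) if isinstance(target, str) else np.asarray(target, np.uint8)
    if len(q) < k or len(t) < k:
        return None
    rt = _seq.revcomp_codes(t)
    qk = _seq.kmer_codes(q, k)
    tk = _seq.kmer_codes(rt, k)
    tvalid = np.flatnonzero(tk >= 0)
    qvalid = np.flatnonzero(qk >= 0)
    if len(tvalid) == 0 or len(qvalid) == 0:
        return None
    order = np.argsort(tk[tvalid], kind="stable")
    t_sorted = tk[tvalid][order]
    t_pos = tvalid[order]
    qcodes = qk[qvalid]
    los = np.searchsorted(t_sorted, qcodes, "left")
    his = np.searchsorted(t_sorted, qcodes, "right")
    hit_q = np.flatnonzero(his > los)
    # seed diagonals: d = q_pos - rt_pos; a diagonal can carry several
    # distinct alignments, so keep every seed and skip those covered by
    # an earlier extension on the same diagonal
    diags: dict[int, list[int]] = {}
    for i in hit_q:
        qp = int(qvalid[i])
        for tp in t_pos[los[i] : his[i]]:
            diags.setdefault(qp - int(tp), []).append(qp)
    best: RCAlignment | None = None
    best_key = None
    for d in sorted(diags):
        q_lo = max(0, d)
        q_hi = min(len(q), d + len(rt))
        qs = q[q_lo:q_hi]
        ts = rt[q_lo - d : q_hi - d]
        match = (qs == ts) & (qs != 4)
        covered_until = q_lo
        for seed_q in sorted(diags[d]):
            if seed_q < covered_until:
                continue
            s0 = seed_q - q_lo
            lo_, hi_, nmatch = _xdrop_segment(match, s0, s0 + k, xdrop)
            covered_until = q_lo + hi_
            length = hi_ - lo_
            if length < min_len or nmatch / length < min_identity:
                continue
            aq_start = q_lo + lo_
            aq_end = q_lo + hi_
            if must_span is not None and not (aq_start <= must_span < aq_end):
                continue
            rt_start = aq_start - d
            rt_end = aq_end - d
            cand = RCAlignment(
                q_start=aq_start,
                q_end=aq_end,
                t_start=len(t) - rt_end,
                t_end=len(t) - rt_start,
                matches=nmatch,
            )
            key = (-cand.matches, cand.t_start, cand.q_start)
            if best is None or key < best_key:
                best, best_key = cand, key
    return best
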