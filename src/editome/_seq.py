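"""Low-level nucleotide sequence utilities.

Bases are encoded as uint8 codes: A=0, C=1, G=2, T=3, N=4.  All pileup,
alignment and simulation code works on these code arrays; strings appear
only at format boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement: A<->T, C<->G, N->N
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> N)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes (base-4); windows containing N get -1.

    Returns an int64 array of length ``len(codes) - k + 1`` (empty if the
    input is shorter than k).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    # N codes (4) would alias real k-mers; mask any window containing one
    vals = win.astype(np.int64) @ powers
    has_n = (win == N).any(axis=1)
    vals[has_n] = -1
    return vals
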