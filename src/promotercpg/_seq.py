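"""Integer-coded DNA sequences.

Bases are coded A=0, C=1, G=2, T=3; every other letter (N and the rarer IUPAC
ambiguity codes) maps to 4 and is treated as missing by all counters.
Lower-case (soft-masked) input is upper-cased on encode.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T, N = 0, 1, 2, 3, 4

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case DNA string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (case-preserving, N self-complementary)."""
    return seq.translate(_COMP_STR)[::-1]


def base_freq_array(freqs) -> np.ndarray:
    """Coerce base frequencies to a length-4 array in A,C,G,T order.

    Accepts a mapping with keys A/C/G/T or a length-4 sequence already in
    that order. Validates non-negativity and sum-to-one.
    """
    if hasattr(freqs, "keys"):
        arr = np.array([float(freqs[b]) for b in BASES], dtype=float)
    else:
        arr = np.asarray(freqs, dtype=float)
    if arr.shape != (4,):
        raise ValueError("base frequencies must have exactly 4 entries (A,C,G,T)")
    if (arr < 0).any():
        raise ValueError("base frequencies must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"base frequencies must sum to 1, got {arr.sum()!r}")
    return arr
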