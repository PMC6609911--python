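"""Compact nucleotide encoding shared across the package.

Bases are held as uint8 codes: A,C,G,T -> 0..3, gap '-' -> 4, anything
else (N, IUPAC ambiguity) -> 255 (missing). Codes keep per-read work in
numpy; strings appear only at file boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
GAP_CODE = 4
MISSING = 255

_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("-")] = GAP_CODE

_DECODE = np.full(256, ord("N"), dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _DECODE[_i] = ord(_b)
_DECODE[GAP_CODE] = ord("-")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


COMPLEMENT = np.array([3, 2, 1, 0, GAP_CODE], dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N preserved)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "-": "-", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq.upper()))
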