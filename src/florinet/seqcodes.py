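"""Nucleotide alphabet encoding shared across modules.

Codes: A=0, C=1, G=2, T=3, N=4 (invalid/ambiguous), 5 = illegal character.
Complement of a valid code b is 3-b, so reverse complement is cheap on arrays.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_CODE = np.full(256, 5, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_DECODE = np.frombuffer(b"ACGTN?", dtype=np.uint8)

_COMP = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0..T=3, N=4, other=5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 5)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case-insensitive input upper out)."""
    return seq.upper().translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out
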