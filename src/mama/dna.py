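"""Small DNA-alphabet helpers shared across modules.

Sequences are uppercase strings over ``{A, C, G, T, N}``.  For vectorized
scoring they are encoded as ``uint8`` codes A=0, C=1, G=2, T=3; ``N`` is
encoded as 4 and never compares equal to a candidate base.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-code translation table: A/C/G/T -> 0..3, N -> 4
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside the alphabet."""
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(
            f"{context}: invalid characters {sorted(bad)!r}; allowed: {ALPHABET}"
        )
    return seq


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"invalid character in sequence {seq!r}")
    return codes


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
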