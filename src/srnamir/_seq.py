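"""Nucleotide-sequence helpers shared by all pipeline stages.

Sequences are handled in DNA space internally (T, not U); U on input is mapped
to T. All coordinates are 0-based half-open unless a function says otherwise.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

#: integer encoding used by the folding DP: A=0, C=1, G=2, T/U=3
_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class SequenceError(ValueError):
    """Raised on sequences containing characters outside {A,C,G,T,U}."""


def normalize(seq: str) -> str:
    """Upper-case ``seq`` and map U to T; reject ambiguous characters."""
    s = seq.upper().replace("U", "T")
    if not s:
        return s
    for ch in set(s):
        if ch not in "ACGT":
            raise SequenceError(f"invalid nucleotide {ch!r} in sequence")
    return s


def is_valid(seq: str) -> bool:
    try:
        normalize(seq)
    except SequenceError:
        return False
    return True


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (accepts U, returns T)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence as uint8 (A=0, C=1, G=2, T=3)."""
    s = normalize(seq)
    return np.fromiter((_ENCODE[c] for c in s), dtype=np.uint8, count=len(s))


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble pairing between two bases (DNA letters)."""
    pair = {a.upper().replace("U", "T"), b.upper().replace("U", "T")}
    return pair in ({"A", "T"}, {"C", "G"}, {"G", "T"})
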