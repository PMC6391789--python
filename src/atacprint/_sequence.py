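"""Small DNA-sequence helpers shared across modules.

Sequences are handled in two forms: plain ``str`` of ACGT (possibly with
ambiguity codes, which are treated as invalid for word extraction) and
integer-encoded ``numpy`` arrays with A=0, C=1, G=2, T=3, invalid=-1.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0,C=1,G=2,T=3; other = -1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on integer codes; -1 (invalid) stays -1."""
    out = codes[::-1].copy()
    valid = out >= 0
    out[valid] = 3 - out[valid]
    return out


def word_index(codes: np.ndarray) -> int:
    """Pack a length-k code vector into a base-4 integer (A=0..T=3).

    Caller must ensure all codes are valid (>= 0).
    """
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def all_words(k: int) -> list[str]:
    """All 4^k DNA words of length k in lexicographic order."""
    words = [""]
    for _ in range(k):
        words = [w + b for w in words for b in BASES]
    return words
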