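"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-level lookup: A/C/G/T -> 0..3, anything else -> -1 (treated as N)
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0, C=1, G=2, T=3, other=-1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_seq(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random sequence with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(BASES[c] for c in codes)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
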