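"""Small DNA sequence utilities shared across the package.

Sequences are plain Python strings over A/C/G/T (lowercase allowed for
masked bases); numpy uint8 code arrays (A=0, C=1, G=2, T=3) are used
internally where vectorization pays off.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# ASCII -> 2-bit code lookup (case-insensitive); 4 marks anything else.
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 code array (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> uppercase sequence string."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def random_seq(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
) -> str:
    """Independent per-base substitutions and single-base indels.

    Used for divergent flank/monomer generation, not for read error
    simulation (which has its own model with homopolymer handling).
    """
    codes = encode(seq)
    n = codes.size
    if sub_rate > 0:
        hit = rng.random(n) < sub_rate
        # offset 1..3 guarantees a different base
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    if indel_rate <= 0:
        return decode(codes)
    out = []
    for c in codes:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        out.append(int(c))
        if r >= indel_rate / 2 and r < indel_rate:
            out.append(int(rng.integers(0, 4)))  # insertion
    return decode(np.asarray(out, dtype=np.uint8))


def rotate(seq: str, cut: int) -> str:
    """Linearize a circular sequence starting at ``cut``."""
    cut %= len(seq)
    return seq[cut:] + seq[:cut]
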