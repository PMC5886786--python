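"""Exact k-mer counting with canonical orientation.

k-mers are stored as the lexicographic minimum of the two orientations
(2-bit packed for k <= 31, so both strands of the data are counted in
one table).  A vectorized rolling encoder keeps counting read sets of
millions of bases fast; a string-dict fallback handles k > 31 (the
50-mer ChIP enrichment tables).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqs import encode, revcomp

VECTOR = "vector"
CENY = "ceny"
OTHER = "other"


def _roll_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical and forward 2-bit hashes of every valid window.

    Windows containing non-ACGT codes are marked invalid with hash
    2**63 (larger than any real k-mer hash for k <= 31).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    comp = (3 - codes).astype(np.uint64)  # complement; junk for sentinel 4
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + n]
        # reverse complement read right-to-left
        rev = (rev << np.uint64(2)) | comp[k - 1 - j : k - 1 - j + n]
    bad = codes > 3
    if bad.any():
        nb = np.cumsum(np.concatenate(([0], bad.astype(np.int64))))
        invalid = (nb[k:] - nb[:-k]) > 0
        sentinel = np.uint64(1) << np.uint64(63)
        fwd = np.where(invalid, sentinel, fwd)
        rev = np.where(invalid, sentinel, rev)
    return np.minimum(fwd, rev), fwd


def encode_kmer(kmer: str) -> np.uint64:
    """Canonical 2-bit hash of one k-mer string (k <= 31)."""
    canon, _ = _roll_hashes(encode(kmer), len(kmer))
    return canon[0]


def _windows(seqs: list[str] | str, k: int) -> np.ndarray:
    """Canonical hashes of all k-mer windows across one or many sequences."""
    if isinstance(seqs, str):
        seqs = [seqs]
    sep = np.array([4], dtype=np.uint8)
    parts: list[np.ndarray] = []
    for s in seqs:
        if len(s) >= k:
            parts.append(encode(s))
            parts.append(sep)
    if not parts:
        return np.empty(0, dtype=np.uint64)
    codes = np.concatenate(parts)
    canon, _ = _roll_hashes(codes, k)
    sentinel = np.uint64(1) << np.uint64(63)
    return canon[canon != sentinel]


@dataclass
class KmerTable:
    """Canonical k-mer counts (sorted hash array + parallel counts)."""

    k: int
    kmers: np.ndarray  # sorted uint64 canonical hashes
    counts: np.ndarray
    source: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        return self.get_hash(encode_kmer(kmer))

    def get_hash(self, h: np.uint64) -> int:
        i = int(np.searchsorted(self.kmers, h))
        if i < self.kmers.size and self.kmers[i] == h:
            return int(self.counts[i])
        return 0

    def depths(self, hashes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.kmers, hashes)
        idx = np.minimum(idx, self.kmers.size - 1)
        hit = self.kmers[idx] == hashes
        out = np.where(hit, self.counts[idx], 0)
        return out.astype(np.int64)


def count_kmers(seqs: list[str] | str, k: int = 21, source: str = "") -> KmerTable:
    """Exact canonical k-mer counts over one or many sequences (k <= 31)."""
    if k > 31:
        raise ValueError("use count_kmers_long for k > 31")
    w = _windows(seqs, k)
    kmers, counts = np.unique(w, return_counts=True)
    return KmerTable(k=k, kmers=kmers, counts=counts, source=source)


def count_kmers_long(seqs: list[str] | str, k: int = 50) -> Counter:
    """String-dict canonical k-mer counts for large k (e.g. 50-mers)."""
    if isinstance(seqs, str):
        seqs = [seqs]
    out: Counter = Counter()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            rc = revcomp(km)
            out[min(km, rc)] += 1
    return out


@dataclass
class KmerLabels:
    """vector/ceny/other labels for the k-mers of a table."""

    k: int
    vector_set: np.ndarray  # sorted canonical hashes
    ceny_set: np.ndarray
    labels: dict = field(default_factory=dict)

    def label_hash(self, h: np.uint64) -> str:
        if _in_sorted(self.vector_set, h):
            return VECTOR
        if _in_sorted(self.ceny_set, h):
            return CENY
        return OTHER

    def label(self, kmer: str) -> str:
        return self.label_hash(encode_kmer(kmer))

    def label_all(self, hashes: np.ndarray) -> np.ndarray:
        """Vectorized labels: 0=vector, 1=ceny, 2=other."""
        out = np.full(hashes.size, 2, dtype=np.int8)
        out[_isin_sorted(self.ceny_set, hashes)] = 1
        out[_isin_sorted(self.vector_set, hashes)] = 0
        return out


def _in_sorted(arr: np.ndarray, h: np.uint64) -> bool:
    i = int(np.searchsorted(arr, h))
    return i < arr.size and arr[i] == h


def _isin_sorted(arr: np.ndarray, hashes: np.ndarray) -> np.ndarray:
    if arr.size == 0:
        return np.zeros(hashes.size, dtype=bool)
    idx = np.minimum(np.searchsorted(arr, hashes), arr.size - 1)
    return arr[idx] == hashes


def build_labels(vector: str, hor_reference: str, k: int = 21) -> KmerLabels:
    """Label k-mers by exact (either-orientation) match to the cloning
    vector or to the canonical HOR repeat."""
    vec = np.unique(_windows(vector, k))
    # the HOR repeat is tandem: include junction k-mers of unit+unit
    ceny = np.unique(_windows(hor_reference + hor_reference[: k - 1], k))
    return KmerLabels(k=k, vector_set=vec, ceny_set=ceny)
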