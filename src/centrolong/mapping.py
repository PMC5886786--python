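"""Minimal seed-and-extend short-read mapper.

Seeds are exact 31-mers hashed over the reference; candidate diagonals
are refined with edlib.  Mapping quality is binary: 60 for a unique
best placement, 0 when the best alignment score is achieved at more
than one reference location (the multi-mapping case that dominates
inside near-identical tandem repeats).  This is exactly the behaviour
the mapQ >= 20 filters downstream rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import cigar_ops, infix_align
from .seqs import revcomp


def mapq_to_prob(q: float) -> float:
    """Probability that a placement with phred-scaled quality q is correct."""
    return 1.0 - 10.0 ** (-q / 10.0)


@dataclass
class MappedRead:
    read_id: str
    ref_start: int
    ref_end: int  # half-open
    strand: str
    mapq: int
    nm: int  # edit distance
    cigar: str
    oriented_seq: str  # read sequence on the reference strand


class ShortReadMapper:
    """Maps short reads against a single reference sequence."""

    def __init__(
        self,
        reference: str,
        k: int = 31,
        seed_stride: int = 16,
        max_divergence: float = 0.25,
    ) -> None:
        self.reference = reference.upper()
        self.k = k
        self.seed_stride = seed_stride
        self.max_divergence = max_divergence
        self.index: dict[str, list[int]] = {}
        ref = self.reference
        for i in range(len(ref) - k + 1):
            self.index.setdefault(ref[i : i + k], []).append(i)

    def _candidates(self, seq: str) -> set[tuple[str, int]]:
        k = self.k
        cands: set[tuple[str, int]] = set()
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            qps = list(range(0, max(len(oriented) - k, 0) + 1, self.seed_stride))
            for qp in qps:
                for rp in self.index.get(oriented[qp : qp + k], ()):
                    cands.add((strand, rp - qp))
        return cands

    def map_read(self, seq: str, read_id: str = "read") -> MappedRead | None:
        seq = seq.upper()
        if len(seq) < self.k:
            return None
        ref = self.reference
        pad = max(20, int(self.max_divergence * len(seq)))
        hits: list[tuple[int, int, int, str, int]] = []  # (nm, start, end, strand, wstart)
        for strand, diag in self._candidates(seq):
            ws = max(0, diag - pad)
            we = min(len(ref), diag + len(seq) + pad)
            oriented = seq if strand == "+" else revcomp(seq)
            aln = infix_align(oriented, ref[ws:we])
            if aln is None:
                continue
            hits.append(
                (aln.edit_distance, ws + aln.target_start, ws + aln.target_end + 1,
                 strand, ws)
            )
        if not hits:
            return None
        best_nm = min(h[0] for h in hits)
        if best_nm > self.max_divergence * len(seq):
            return None
        # dedupe equal-score placements that are really the same locus
        placements: list[tuple[int, int, str]] = []
        for nm, s, e, strand, _ in sorted(hits):
            if nm != best_nm:
                break
            if all(abs(s - ps) > 10 or strand != pst for ps, _, pst in placements):
                placements.append((s, e, strand))
        s, e, strand = placements[0]
        mapq = 60 if len(placements) == 1 else 0
        oriented = seq if strand == "+" else revcomp(seq)
        # re-align within the chosen window to get the path
        aln = infix_align(oriented, ref[max(0, s - 5) : e + 5])
        assert aln is not None
        off = max(0, s - 5)
        return MappedRead(
            read_id,
            off + aln.target_start,
            off + aln.target_end + 1,
            strand,
            mapq,
            aln.edit_distance,
            aln.cigar,
            oriented,
        )


BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
DEL_IDX = 4


def pileup(
    mapped: list[MappedRead], ref_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Substitution-level pileup: per-position base/deletion counts and
    spanning-read coverage.  Read insertions are not counted."""
    counts = np.zeros((ref_len, 5), dtype=np.int64)
    coverage = np.zeros(ref_len, dtype=np.int64)
    for m in mapped:
        coverage[m.ref_start : m.ref_end] += 1
        t = m.ref_start
        q = 0
        for n, op in cigar_ops(m.cigar):
            if op in "=XM":
                for j in range(n):
                    b = BASE_IDX.get(m.oriented_seq[q + j])
                    if b is not None:
                        counts[t + j, b] += 1
                t += n
                q += n
            elif op == "D":
                counts[t : t + n, DEL_IDX] += 1
                t += n
            elif op == "I":
                q += n
    return counts, coverage
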