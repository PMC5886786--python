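"""Thin wrappers around edlib pairwise alignment.

Conventions: ``query`` and ``target`` follow edlib's roles; in read-vs-
reference alignments the read is the query.  In edlib CIGAR strings
``=``/``X`` consume both sequences, ``D`` consumes the target only and
``I`` the query only (verified against edlib's output convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .seqs import revcomp

_CIG = re.compile(r"(\d+)([=XIDM])")


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


@dataclass
class Alignment:
    """A pairwise alignment of query against target."""

    edit_distance: int
    cigar: str
    target_start: int
    target_end: int  # inclusive, edlib convention
    strand: str = "+"

    @property
    def n_columns(self) -> int:
        return sum(n for n, _ in cigar_ops(self.cigar))

    @property
    def n_matches(self) -> int:
        return sum(n for n, op in cigar_ops(self.cigar) if op == "=")

    @property
    def identity(self) -> float:
        cols = self.n_columns
        return self.n_matches / cols if cols else 0.0


def _run(query: str, target: str, mode: str) -> Alignment | None:
    res = edlib.align(query.upper(), target.upper(), mode=mode, task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        return None
    start, end = res["locations"][0]
    return Alignment(res["editDistance"], res["cigar"], start, end)


def global_align(query: str, target: str) -> Alignment:
    """End-to-end alignment (edlib NW)."""
    aln = _run(query, target, "NW")
    assert aln is not None
    return aln


def infix_align(query: str, target: str) -> Alignment | None:
    """Best alignment of the whole query inside the target (edlib HW)."""
    return _run(query, target, "HW")


def infix_align_both_strands(query: str, target: str) -> Alignment | None:
    """Infix alignment trying both query strands; best by edit distance.

    Ties are broken toward the forward strand.
    """
    fwd = infix_align(query, target)
    rev = infix_align(revcomp(query), target)
    if fwd is None:
        best = rev
    elif rev is None or fwd.edit_distance <= rev.edit_distance:
        best = fwd
    else:
        best = rev
    if best is rev and rev is not None:
        rev.strand = "-"
    return best


def identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if not a or not b:
        return 0.0
    return global_align(a, b).identity


def edit_distance(a: str, b: str) -> int:
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="distance")
    return res["editDistance"]
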