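"""Full-length read selection and reorientation.

A clone read is "full length" when it traverses the entire linearized
circular construct, which is recognized by the presence of (at least
3 kb of) cloning-vector sequence.  Because the transposase cut point is
random, a full-length read is an arbitrary rotation of the circle;
selected reads are rotated to a common forward frame that starts at the
vector-to-insert transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import infix_align
from .seqs import revcomp, rotate

log = logging.getLogger(__name__)


@dataclass
class VectorAnchor:
    read_id: str
    matched_span_bp: int
    read_interval: tuple[int, int]  # 0-based half-open, on the read as given
    strand: str
    vector_offset: int  # offset of the first matched tile within the vector


@dataclass
class SelectionParams:
    min_vector_span: int = 3_000
    insert_min: int | None = None
    insert_max: int | None = None
    anchor_prefix: int = 3_000
    tile: int = 500  # vector tile size for span estimation
    tile_max_divergence: float = 0.40

    def __post_init__(self) -> None:
        if (
            self.insert_min is not None
            and self.insert_max is not None
            and self.insert_min >= self.insert_max
        ):
            raise ValueError("insert_min must be < insert_max")


@dataclass
class SelectedRead:
    read_id: str
    forward_sequence: str  # rotation starting at the vector->insert junction
    insert_span: tuple[int, int]
    source_strand: str


def find_vector_anchor(
    read: str,
    vector: str,
    read_id: str = "read",
    params: SelectionParams | None = None,
) -> VectorAnchor | None:
    """Locate vector sequence in a read, on either strand.

    The vector is scanned as non-overlapping tiles so that a vector
    split across the ends of a rotated read is still fully credited.
    Returns None unless >= ``min_vector_span`` vector bases match.
    """
    if not read or not vector:
        raise ValueError("empty read or vector")
    p = params or SelectionParams()
    tiles = [
        (off, vector[off : off + p.tile])
        for off in range(0, len(vector) - p.tile + 1, p.tile)
    ]
    best = None
    for strand in "+-":
        target = read if strand == "+" else revcomp(read)
        span = 0
        score = 0
        hits: list[tuple[int, int, int]] = []  # (vector_off, read_start, read_end)
        for off, tile in tiles:
            aln = infix_align(tile, target)
            if aln is None or aln.edit_distance > p.tile_max_divergence * p.tile:
                continue
            span += p.tile
            score += p.tile - aln.edit_distance
            hits.append((off, aln.target_start, aln.target_end + 1))
        if span < p.min_vector_span or not hits:
            continue
        lo = min(h[1] for h in hits)
        hi = max(h[2] for h in hits)
        if strand == "-":
            lo, hi = len(read) - hi, len(read) - lo
        cand = (score, strand == "+", span, lo, hi, min(h[0] for h in hits))
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    score, is_fwd, span, lo, hi, voff = best
    return VectorAnchor(read_id, span, (lo, hi), "+" if is_fwd else "-", voff)


def _locate(query: str, target: str, max_divergence: float = 0.45):
    aln = infix_align(query, target)
    if aln is None or aln.edit_distance > max_divergence * len(query):
        return None
    return aln


def reorient(read: str, vector: str, anchor_prefix: int = 3_000) -> SelectedRead | None:
    """Rotate a forward-strand full-length read to start at the
    vector->insert junction.

    The last ``anchor_prefix`` bases of the vector immediately precede
    the insert on the circle; the rotation starts right after their
    match.  If the random cut fell inside that window, the read is first
    rotated to the vector start (found via the vector head) and retried.
    """
    vtail = vector[-anchor_prefix:]
    aln = _locate(vtail, read)
    if aln is None:
        vhead = vector[:anchor_prefix]
        head = _locate(vhead, read)
        if head is None:
            return None
        read = rotate(read, head.target_start)
        aln = _locate(vtail, read)
        if aln is None:
            return None
    forward = rotate(read, aln.target_end + 1)
    head = _locate(vector[:anchor_prefix], forward)
    insert_end = head.target_start if head is not None else len(forward) - len(vector)
    return SelectedRead("", forward, (0, max(insert_end, 0)), "+")


def select_full_length(
    reads: list[tuple[str, str]],
    vector: str,
    params: SelectionParams | None = None,
) -> list[SelectedRead]:
    """Keep vector-anchored reads whose implied insert length is within
    [insert_min, insert_max], reoriented to the common forward frame.

    When the bounds are not supplied they default to the modal
    full-length peak of the yield curve +/- 10%.
    """
    p = params or SelectionParams()
    if p.insert_min is None or p.insert_max is None:
        mode = modal_read_length([seq for _, seq in reads])
        lo = int(mode * 0.9) - len(vector)
        hi = int(mode * 1.1) - len(vector)
        p = SelectionParams(p.min_vector_span, max(lo, 1), hi, p.anchor_prefix)
    selected: list[SelectedRead] = []
    for rid, seq in reads:
        insert_len = len(seq) - len(vector)
        if not p.insert_min <= insert_len <= p.insert_max:
            continue
        anchor = find_vector_anchor(seq, vector, rid, p)
        if anchor is None:
            continue
        oriented = seq if anchor.strand == "+" else revcomp(seq)
        sel = reorient(oriented, vector, p.anchor_prefix)
        if sel is None:
            continue
        sel.read_id = rid
        sel.source_strand = anchor.strand
        selected.append(sel)
    if not selected:
        log.warning("no full-length reads selected from %d reads", len(reads))
    return selected


def yield_curve(reads: list[str] | list[tuple[str, str]]) -> pd.DataFrame:
    """Cumulative megabase yield against sorted read length.

    The cumulative column counts bases in reads of length >= the row's
    length, mirroring the yield plots used to pick length thresholds.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    if not seqs:
        return pd.DataFrame(columns=["read_length", "cumulative_mb"])
    lengths = np.sort(np.array([len(s) for s in seqs]))
    cum = np.cumsum(lengths) / 1e6
    return pd.DataFrame({"read_length": lengths, "cumulative_mb": cum})


def modal_read_length(seqs: list[str], nbins: int = 50) -> int:
    """Length-weighted modal read length (the full-length yield peak)."""
    lengths = np.array([len(s) for s in seqs])
    if lengths.size == 0:
        raise ValueError("no reads")
    if lengths.size == 1:
        return int(lengths[0])
    hist, edges = np.histogram(lengths, bins=nbins, weights=lengths)
    i = int(np.argmax(hist))
    in_bin = lengths[(lengths >= edges[i]) & (lengths <= edges[i + 1])]
    return int(np.median(in_bin))
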