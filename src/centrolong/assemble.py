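"""Clone-level overlap-layout-consensus assembly of the array.

BAC consensuses are ordered by shared validated single-copy variants
(satVARs): two clones overlap when they carry satVARs with identical
signatures at mutually consistent spacings.  Clones reaching into the
unique p-arm or q-arm sequence are anchored there, fixing the ends of
the layout; the merged array switches between clones at the midpoint of
each overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import infix_align
from . import annotate

log = logging.getLogger(__name__)


@dataclass
class OverlapEvidence:
    bac_a: str
    bac_b: str
    shared: list[tuple[str, str]]  # (variant id in a, variant id in b)
    offset: int  # position of b's origin in a's coordinates
    residual: int  # max spacing deviation among shared variants
    anchors: tuple[bool, bool] = (False, False)


@dataclass
class ArrayAssembly:
    order: list[str]
    switch_points: list[int]  # assembly coordinates where the source BAC changes
    sequence: str
    components: list[tuple[str, int, int]]  # (bac, start, end) AGP-like
    hor_count: int = 0
    array_length: int = 0
    alpha_satellite_span: int = 0


def find_overlaps(
    bac_satvars: dict[str, list],
    tolerance: int = 200,
) -> list[OverlapEvidence]:
    """Pairwise overlap evidence from shared satVAR signatures.

    Variants match on (kind, ref, alt); the best mutually consistent
    spacing cluster fixes the offset.  Pairs whose matches exist but
    disagree in spacing are rejected and logged.
    """
    names = sorted(bac_satvars)
    out: list[OverlapEvidence] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            matches = []
            for va in bac_satvars[a]:
                for vb in bac_satvars[b]:
                    if (va.kind, va.ref, va.alt) != (vb.kind, vb.ref, vb.alt):
                        continue
                    ka = getattr(va, "spanning_kmer", "")
                    kb = getattr(vb, "spanning_kmer", "")
                    # the 21-mer context is the variant's identity; require
                    # agreement whenever both sides carry one
                    if ka and kb and ka != kb:
                        continue
                    matches.append(
                            (va.name, vb.name,
                             va.consensus_position - vb.consensus_position)
                        )
            if not matches:
                continue
            diffs = np.array([m[2] for m in matches])
            # best spacing-consistent cluster
            best_members: list[int] = []
            for j, d in enumerate(diffs):
                members = [k for k, d2 in enumerate(diffs) if abs(d2 - d) <= tolerance]
                if len(members) > len(best_members):
                    best_members = members
            if len(best_members) < len(set((m[0] for m in matches))) and len(
                best_members
            ) == 1 and len(matches) > 1:
                log.warning(
                    "rejecting %s-%s overlap: inconsistent satVAR spacings", a, b
                )
                continue
            offset = int(np.median(diffs[best_members]))
            residual = int(np.max(np.abs(diffs[best_members] - offset)))
            shared = [(matches[k][0], matches[k][1]) for k in best_members]
            out.append(OverlapEvidence(a, b, shared, offset, residual))
    return out


def anchor_arms(
    bac_consensuses: dict[str, str],
    p_anchor: str,
    q_anchor: str,
    min_identity: float = 0.95,
    min_span: int = 5_000,
    tile: int = 1_000,
) -> dict[str, set[str]]:
    """Flag clones whose sequence aligns to the p-arm or q-arm anchor at
    >= ``min_identity`` over >= ``min_span`` bases (tile-counted)."""
    flags: dict[str, set[str]] = {name: set() for name in bac_consensuses}
    for name, cons in bac_consensuses.items():
        for side, anchor in (("p", p_anchor), ("q", q_anchor)):
            if not anchor:
                continue
            span = 0
            for off in range(0, len(anchor) - tile + 1, tile):
                aln = infix_align(anchor[off : off + tile], cons)
                if aln is not None and aln.identity >= min_identity:
                    span += tile
            if span >= min_span:
                flags[name].add(side)
    return flags


def order_and_merge(
    bac_consensuses: dict[str, str],
    evidence: list[OverlapEvidence],
    anchors: dict[str, set[str]],
    hor_reference: str | None = None,
    monomer_reference: str | None = None,
    tolerance: int = 500,
) -> ArrayAssembly:
    """Resolve the unique p->q clone order and merge at overlap midpoints.

    A single shared satVAR suffices for an edge: placements are chained
    out from the arm-anchored end clone and every placement is checked
    for spacing contradictions (satVAR signatures carry their 21-mer
    context, so spurious matches cannot form).  Disconnected or
    contradictory evidence is an error.
    """
    names = sorted(bac_consensuses)
    p_terms = [n for n in names if "p" in anchors.get(n, set())]
    q_terms = [n for n in names if "q" in anchors.get(n, set())]
    if len(p_terms) != 1 or len(q_terms) != 1:
        raise ValueError(
            f"need exactly one p-terminal and one q-terminal clone, "
            f"got p={p_terms} q={q_terms}"
        )
    adj: dict[str, list[tuple[str, int]]] = {n: [] for n in names}
    for ev in evidence:
        # offset = position of bac_b's origin in bac_a's frame
        adj[ev.bac_a].append((ev.bac_b, ev.offset))
        adj[ev.bac_b].append((ev.bac_a, -ev.offset))
    # BFS global offsets from the p-terminal clone
    start = p_terms[0]
    pos: dict[str, int] = {start: 0}
    queue = [start]
    while queue:
        cur = queue.pop(0)
        for nxt, delta in adj[cur]:
            cand = pos[cur] + delta
            if nxt in pos:
                if abs(pos[nxt] - cand) > tolerance:
                    raise ValueError(
                        f"contradictory overlap evidence at {nxt}: "
                        f"offsets {pos[nxt]} vs {cand}"
                    )
            else:
                pos[nxt] = cand
                queue.append(nxt)
    missing = set(names) - set(pos)
    if missing:
        raise ValueError(f"overlap graph disconnected; unplaced clones: {sorted(missing)}")
    order = sorted(names, key=lambda n: pos[n])
    if order[-1] != q_terms[0]:
        raise ValueError("q-terminal clone is not last in the resolved order")
    base = pos[order[0]]
    offsets = {n: pos[n] - base for n in order}
    # merge at overlap midpoints
    parts: list[tuple[str, int, int]] = []  # (bac, local start, local end)
    switches: list[int] = []
    cursor_global = 0
    for i, name in enumerate(order):
        o = offsets[name]
        length = len(bac_consensuses[name])
        if i + 1 < len(order):
            nxt = order[i + 1]
            ov_start = offsets[nxt]
            ov_end = o + length
            if ov_end <= ov_start:
                raise ValueError(f"no positive overlap between {name} and {nxt}")
            switch = (ov_start + ov_end) // 2
        else:
            switch = o + length
        parts.append((name, cursor_global - o, switch - o))
        if i + 1 < len(order):
            switches.append(switch)
        cursor_global = switch
    seq_parts = []
    components = []
    acc = 0
    for name, ls, le in parts:
        ls = max(0, ls)
        piece = bac_consensuses[name][ls:le]
        seq_parts.append(piece)
        components.append((name, acc, acc + len(piece)))
        acc += len(piece)
    merged = "".join(seq_parts)
    asm = ArrayAssembly(order, switches, merged, components)
    if hor_reference:
        instances = annotate.detect_hors(merged, hor_reference)
        asm.hor_count = len(instances)
        if instances:
            asm.array_length = instances[-1].end - instances[0].start
            asm.alpha_satellite_span = asm.array_length
            if monomer_reference:
                flanks = annotate.detect_monomeric_flanks(
                    merged, monomer_reference,
                    (instances[0].start, instances[-1].end),
                )
                asm.alpha_satellite_span += sum(e - s for s, e in flanks)
    return asm
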