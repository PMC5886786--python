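"""HOR detection, identity, structural classification and haplotyping.

Higher-order repeat (HOR) instances are found by greedy non-overlapping
semi-global tiling of the canonical repeat against the sequence — on
near-identical tandem arrays this matches what a profile-HMM scan would
return while staying trivial to verify.  Haplotypes are the allele
combinations at array-frequent variant columns; blocks are maximal runs
dominated by one haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .align import cigar_ops, global_align, identity as global_identity, infix_align

log = logging.getLogger(__name__)


@dataclass
class HORInstance:
    index: int
    start: int
    end: int  # 0-based half-open
    identity_to_reference: float
    length_class: str = "canonical"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class HaplotypeAssignment:
    labels: list[str]  # per-HOR haplotype label
    blocks: list[tuple[int, int, str]]  # (start_hor, end_hor, dominant label)
    haplotypes: dict[str, tuple] = field(default_factory=dict)


def detect_hors(
    sequence: str,
    hor_reference: str,
    min_identity: float = 0.8,
    max_absorb: int | None = None,
) -> list[HORInstance]:
    """Greedy non-overlapping tiling of best semi-global matches of the
    canonical HOR unit, keeping hits at >= ``min_identity``.

    Interior gaps between adjacent instances (up to ``max_absorb``,
    default half the reference length) are absorbed into the neighbour
    with the weaker reference alignment: structural length variants
    align partially and leave their insert as such a gap, which belongs
    to them.  The array region between first and last instance is then
    covered contiguously.
    """
    if not hor_reference:
        raise ValueError("empty HOR reference")
    absorb = max_absorb if max_absorb is not None else len(hor_reference) // 2
    found: list[tuple[int, int, float]] = []
    stack = [(0, len(sequence))]
    min_seg = int(0.5 * len(hor_reference))
    while stack:
        s, e = stack.pop()
        if e - s < min_seg:
            continue
        aln = infix_align(hor_reference, sequence[s:e])
        if aln is None or aln.identity < min_identity:
            continue
        hit_s, hit_e = s + aln.target_start, s + aln.target_end + 1
        found.append((hit_s, hit_e, aln.identity))
        stack.append((s, hit_s))
        stack.append((hit_e, e))
    found.sort()
    instances = [HORInstance(i, s, e, ident) for i, (s, e, ident) in enumerate(found)]
    # pass 1: clear identity difference -> the weaker (truncated) side
    # owns the gap; pass 2: ties (adjacent structural units) split the
    # remaining gap so lengths equalize
    for a, b in zip(instances, instances[1:]):
        gap = b.start - a.end
        if not 0 < gap <= absorb:
            continue
        d = a.identity_to_reference - b.identity_to_reference
        if d <= -0.02:
            a.end = b.start
        elif d >= 0.02:
            b.start = a.end
    for a, b in zip(instances, instances[1:]):
        gap = b.start - a.end
        if 0 < gap <= absorb:
            to_a = int(min(max((b.length + gap - a.length) / 2, 0), gap))
            a.end += to_a
            b.start = a.end
    return instances


_AFFINE = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def _affine_identity(a: str, b: str) -> float:
    aln = _AFFINE.align(a.upper(), b.upper())[0]
    c = aln.counts()
    return c.identities / (c.identities + c.mismatches + c.gaps)


def pairwise_identity(
    instances: list[HORInstance],
    sequence: str,
    engine: str = "affine",
) -> tuple[float, np.ndarray]:
    """Mean pairwise identity over all instance pairs.

    ``engine="affine"`` (default) scores each pair with a global
    affine-gap alignment; ``engine="edit"`` uses unit-cost global
    alignment, which is orders of magnitude faster on multi-kb units
    and differs only in how gap runs are placed.  Identity = matches /
    alignment columns either way.
    """
    if len(instances) < 2:
        raise ValueError("need >= 2 instances")
    score = _affine_identity if engine == "affine" else global_identity
    seqs = [sequence[h.start : h.end] for h in instances]
    n = len(seqs)
    mat = np.ones((n, n))
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            ident = score(seqs[i], seqs[j])
            mat[i, j] = mat[j, i] = ident
            pairs.append(ident)
    return float(np.mean(pairs)), mat


@dataclass
class StructuralReport:
    clusters: list[list[int]]  # runs of structural instance indices
    intercluster_bp: list[int]


def classify_structural(
    instances: list[HORInstance],
    canonical_length: int,
    tolerance: int = 100,
) -> StructuralReport:
    """Length-classify instances in place and report structural clusters
    (runs of adjacent structural units) and the gaps between them."""
    if canonical_length <= 0:
        raise ValueError("canonical_length must be positive")
    for h in instances:
        h.length_class = (
            "structural" if abs(h.length - canonical_length) > tolerance else "canonical"
        )
    clusters: list[list[int]] = []
    for h in instances:
        if h.length_class != "structural":
            continue
        if clusters and clusters[-1][-1] == h.index - 1:
            clusters[-1].append(h.index)
        else:
            clusters.append([h.index])
    gaps = []
    for a, b in zip(clusters, clusters[1:]):
        gaps.append(instances[b[0]].start - instances[a[-1]].end)
    return StructuralReport(clusters, gaps)


def build_variant_matrix(
    sequence: str, instances: list[HORInstance], hor_reference: str
) -> pd.DataFrame:
    """Allele matrix: rows = HOR instances, columns = reference offsets
    where any instance carries a substitution or single-base deletion.

    Multi-base indels (structural insert blocks) do not map to a single
    reference offset and are excluded by construction.
    """
    if not instances:
        raise ValueError("no instances")
    per_unit: list[dict[int, str]] = []
    for h in instances:
        unit = sequence[h.start : h.end].upper()
        aln = global_align(unit, hor_reference.upper())
        diffs: dict[int, str] = {}
        t = q = 0  # t: reference offset, q: unit offset
        for n, op in cigar_ops(aln.cigar):
            if op in "=XM":
                if op == "X":
                    for j in range(n):
                        diffs[t + j] = unit[q + j]
                t += n
                q += n
            elif op == "D":  # unit base(s) absent -> deletion vs reference
                if n == 1:
                    diffs[t] = "-"
                t += n
            elif op == "I":
                q += n
        per_unit.append(diffs)
    columns = sorted({off for d in per_unit for off in d})
    data = {
        off: [d.get(off, hor_reference[off].upper()) for d in per_unit]
        for off in columns
    }
    return pd.DataFrame(data, index=[h.index for h in instances])


def find_frequent_variants(matrix: pd.DataFrame, min_count: int = 4) -> list[int]:
    """Columns whose minor allele occurs in at least ``min_count`` HORs."""
    if matrix.empty:
        raise ValueError("empty variant matrix")
    cols = []
    for col in matrix.columns:
        vc = matrix[col].value_counts()
        if len(vc) > 1 and int(vc.iloc[1:].sum()) >= min_count:
            cols.append(col)
    return cols


def assign_haplotypes(
    matrix: pd.DataFrame, frequent_columns: list[int]
) -> HaplotypeAssignment:
    """Haplotype = allele tuple at the frequent columns; labels numbered
    by first occurrence (H1, H2, ...); blocks are maximal runs in which
    one label holds > 50% frequency."""
    if not frequent_columns:
        raise ValueError("no frequent columns")
    tuples = [tuple(matrix.loc[i, frequent_columns]) for i in matrix.index]
    seen: dict[tuple, str] = {}
    labels = []
    for t in tuples:
        if t not in seen:
            seen[t] = f"H{len(seen) + 1}"
        labels.append(seen[t])
    # runs of identical labels, then absorb length-1 strays sandwiched
    # between runs sharing a dominant label (the block keeps >50%
    # frequency for that label)
    runs: list[list] = []  # [start, end, dominant, counts]
    for i, lab in enumerate(labels):
        if runs and runs[-1][2] == lab:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1, lab])
    changed = True
    while changed and len(runs) > 2:
        changed = False
        for j in range(1, len(runs) - 1):
            a, b, c = runs[j - 1], runs[j], runs[j + 1]
            if a[2] == c[2] and (b[1] - b[0]) == 1:
                merged_len = c[1] - a[0]
                dom_count = (a[1] - a[0]) + (c[1] - c[0])
                if dom_count / merged_len > 0.5:
                    runs[j - 1] = [a[0], c[1], a[2]]
                    del runs[j : j + 2]
                    changed = True
                    break
    blocks = [(s, e, lab) for s, e, lab in runs]
    return HaplotypeAssignment(
        labels, blocks, {v: k for k, v in seen.items()}
    )


def detect_monomeric_flanks(
    sequence: str,
    monomer_reference: str,
    array_interval: tuple[int, int],
    min_identity: float = 0.6,
    join_gap: int | None = None,
) -> list[tuple[int, int]]:
    """Divergent monomeric satellite outside the HOR array: greedy
    monomer tiling at >= ``min_identity``, merged into intervals."""
    if not monomer_reference:
        raise ValueError("monomer reference required")
    join = join_gap if join_gap is not None else len(monomer_reference)
    arr_s, arr_e = array_interval
    out: list[tuple[int, int]] = []
    for seg_s, seg_e in ((0, arr_s), (arr_e, len(sequence))):
        hits: list[tuple[int, int]] = []
        stack = [(seg_s, seg_e)]
        while stack:
            s, e = stack.pop()
            if e - s < int(0.5 * len(monomer_reference)):
                continue
            aln = infix_align(monomer_reference, sequence[s:e])
            if aln is None or aln.identity < min_identity:
                continue
            hs, he = s + aln.target_start, s + aln.target_end + 1
            hits.append((hs, he))
            stack.append((s, hs))
            stack.append((he, e))
        hits.sort()
        merged: list[list[int]] = []
        for hs, he in hits:
            if merged and hs - merged[-1][1] <= join:
                merged[-1][1] = he
            else:
                merged.append([hs, he])
        out.extend((a, b) for a, b in merged)
    return out
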