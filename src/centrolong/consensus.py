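"""Sampled-MSA consensus and polishing for clone long reads.

The consensus protocol: draw several random samples of co-oriented
full-length reads, build a multiple alignment per sample, call a draft
consensus per sample with explicit column rules (majority base; a gap
is honoured only when the runner-up nucleotide is rare), then align the
drafts and call a meta-consensus.  Polishing re-aligns *all* full-length
reads to the consensus, removes weakly covered bases and lowercase-masks
poorly supported ones; short-read polishing applies a stricter 80%-
agreement substitution rule inside unique (non-satellite) regions only.

The multiple aligner is a star MSA: each sequence is globally aligned
to a scaffold sequence (the median-length input); scaffold positions
define the main columns and insertions relative to the scaffold become
left-aligned extra columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import cigar_ops, global_align
from .mapping import ShortReadMapper, pileup
from .rngs import make_rng
from .seqs import BASES, encode

log = logging.getLogger(__name__)

GAP = 4
_SYMBOLS = "ACGT-"
_BASE_IDX = {b: i for i, b in enumerate(_SYMBOLS)}


@dataclass
class SamplePlan:
    reads_per_sample: int = 60
    iterations: int = 10
    seed: int = 0


@dataclass
class ConsensusParams:
    # a gap column is only deleted when the second most frequent symbol
    # (the best nucleotide) is present in fewer than this many sequences
    gap_second_base_min: int = 10
    tie_break: str = "ACGT"


@dataclass
class ColumnProfile:
    """Per-column A/C/G/T/gap counts of a multiple alignment."""

    counts: np.ndarray  # (n_columns, 5)
    depth: int

    @property
    def n_columns(self) -> int:
        return int(self.counts.shape[0])


@dataclass
class MSA:
    profile: ColumnProfile
    rows: list[str] = field(default_factory=list)  # aligned sequences, optional


@dataclass
class PolishedConsensus:
    sequence: str  # lowercase = masked (<50% support)
    coverage: np.ndarray
    support: np.ndarray
    average_coverage: float


# ---------------------------------------------------------------------------
# star MSA


def _align_to_scaffold(seq: str, scaffold: str) -> tuple[np.ndarray, dict[int, str]]:
    """Return (main, ins): per-scaffold-position symbol codes (4 = gap)
    and insertions keyed by the scaffold junction they precede."""
    aln = global_align(seq, scaffold)
    main = np.full(len(scaffold), GAP, dtype=np.uint8)
    qcodes = encode(seq)  # A/C/G/T -> 0..3, anything else 4 (= gap code)
    ins: dict[int, str] = {}
    t = q = 0
    for n, op in cigar_ops(aln.cigar):
        if op in "=XM":
            main[t : t + n] = qcodes[q : q + n]
            t += n
            q += n
        elif op == "D":  # gap in seq against scaffold positions
            t += n
        elif op == "I":  # seq bases between scaffold positions
            ins[t] = ins.get(t, "") + seq[q : q + n].upper()
            q += n
    return main, ins


def build_msa(
    sequences: list[str],
    scaffold_index: int | None = None,
    keep_rows: bool = False,
) -> MSA:
    """Star multiple alignment of co-oriented sequences.

    Every input base lands in exactly one column and column order
    respects each sequence's base order.  Sequences differing more than
    2x in length are rejected (they cannot be globally co-aligned).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = [len(s) for s in sequences]
    if max(lengths) > 2 * min(lengths):
        raise ValueError("sequence lengths differ by more than 2x")
    if scaffold_index is None:
        order = np.argsort(lengths)
        scaffold_index = int(order[len(order) // 2])
    scaffold = sequences[scaffold_index].upper()
    L = len(scaffold)
    aligned: list[tuple[np.ndarray, dict[int, str]]] = []
    for i, seq in enumerate(sequences):
        if i == scaffold_index:
            main = np.array([_BASE_IDX.get(b, GAP) for b in scaffold], dtype=np.uint8)
            aligned.append((main, {}))
        else:
            aligned.append(_align_to_scaffold(seq.upper(), scaffold))
    ins_width = np.zeros(L + 1, dtype=np.intp)
    for _, ins in aligned:
        for j, s in ins.items():
            ins_width[j] = max(ins_width[j], len(s))
    # column k layout: [ins cols before pos 0][pos 0][ins before 1][pos 1]...
    col_of_main = np.zeros(L, dtype=np.intp)
    acc = 0
    for t in range(L):
        acc += ins_width[t]
        col_of_main[t] = acc
        acc += 1
    ncols = acc + ins_width[L]
    counts = np.zeros((ncols, 5), dtype=np.int64)
    rows: list[list[str]] = [["-"] * ncols for _ in sequences] if keep_rows else []
    for r, (main, ins) in enumerate(aligned):
        cols = col_of_main
        np.add.at(counts, (cols, main.astype(np.intp)), 1)
        gap_cols = np.ones(ncols, dtype=bool)
        if keep_rows:
            for t in range(L):
                rows[r][cols[t]] = _SYMBOLS[main[t]]
        # everything not explicitly filled is a gap: count gaps for the
        # insertion columns this sequence does not use
        used = np.zeros(ncols, dtype=bool)
        used[cols] = True
        for j, s in ins.items():
            start = col_of_main[j] - ins_width[j] if j < L else ncols - ins_width[L]
            for x, b in enumerate(s):  # left-aligned
                counts[start + x, _BASE_IDX.get(b, GAP)] += 1
                used[start + x] = True
                if keep_rows:
                    rows[r][start + x] = b
        counts[~used, GAP] += 1
        del gap_cols
    profile = ColumnProfile(counts=counts, depth=len(sequences))
    return MSA(profile=profile, rows=["".join(r) for r in rows] if keep_rows else [])


# ---------------------------------------------------------------------------
# consensus calling


def call_consensus(profile: ColumnProfile, params: ConsensusParams | None = None) -> str:
    """Most prevalent symbol per column; a gap deletes the column only
    when the best nucleotide there is seen in fewer than
    ``gap_second_base_min`` sequences, otherwise that nucleotide is
    called.  Base ties break in fixed A<C<G<T order."""
    p = params or ConsensusParams()
    counts = profile.counts
    if counts.shape[0] == 0:
        raise ValueError("empty profile")
    out: list[str] = []
    order = [_BASE_IDX[b] for b in p.tie_break]
    for col in counts:
        base_counts = [(int(col[i]), i) for i in order]
        top_count, top_base = max(base_counts, key=lambda x: (x[0], -x[1]))
        gap_count = int(col[GAP])
        if top_count == 0 and gap_count == 0:
            log.warning("all-zero MSA column skipped")
            continue
        if gap_count > top_count:
            if top_count < p.gap_second_base_min:
                continue  # gap wins: column deleted
            out.append(BASES[top_base])
        else:
            if top_count == 0:
                continue
            out.append(BASES[top_base])
    return "".join(out)


def iterate_consensus_with_drafts(
    reads: list[str],
    plan: SamplePlan | None = None,
    params: ConsensusParams | None = None,
) -> tuple[str, list[str]]:
    """Random-sampling consensus: per-iteration drafts plus the final
    meta-consensus over an MSA of the drafts."""
    plan = plan or SamplePlan()
    params = params or ConsensusParams()
    if not reads:
        raise ValueError("no reads")
    n_sample = plan.reads_per_sample
    if n_sample > len(reads):
        log.warning(
            "reads_per_sample=%d capped to available %d", n_sample, len(reads)
        )
        n_sample = len(reads)
    rng = make_rng(plan.seed)
    drafts: list[str] = []
    for _ in range(plan.iterations):
        idx = rng.choice(len(reads), size=n_sample, replace=False)
        sample = [reads[i] for i in idx]
        if len(sample) == 1:
            drafts.append(sample[0].upper())
            continue
        msa = build_msa(sample)
        drafts.append(call_consensus(msa.profile, params))
    if len(drafts) == 1:
        return drafts[0], drafts
    # The gap rule keeps its absolute 10-read threshold at the meta MSA
    # (depth 10), where it reduces to a strict majority: a column is kept
    # only when more drafts call a base than a gap.  Rescaling the
    # threshold to the meta depth retains correlated draft insertion
    # errors and measurably degrades the meta-consensus.
    meta = call_consensus(build_msa(drafts).profile, params)
    return meta, drafts


def iterate_consensus(
    reads: list[str],
    plan: SamplePlan | None = None,
    params: ConsensusParams | None = None,
) -> str:
    meta, _ = iterate_consensus_with_drafts(reads, plan, params)
    return meta


# ---------------------------------------------------------------------------
# polishing


def polish(consensus: str, reads: list[str]) -> PolishedConsensus:
    """Long-read polish: re-align every full-length read to the
    consensus; drop bases covered by fewer than half the average
    coverage, replace bases where the read majority disagrees, and
    lowercase-mask retained bases with <50% read support."""
    if not consensus:
        raise ValueError("empty consensus")
    if not reads:
        raise ValueError("no reads to polish with")
    L = len(consensus)
    counts = np.zeros((L, 5), dtype=np.int64)
    coverage = np.zeros(L, dtype=np.int64)
    cons_codes = [_BASE_IDX.get(b, GAP) for b in consensus.upper()]
    for seq in reads:
        main, _ = _align_to_scaffold(seq, consensus.upper())
        covered = np.flatnonzero(main != GAP)
        if covered.size == 0:
            continue
        lo, hi = int(covered[0]), int(covered[-1]) + 1
        coverage[lo:hi] += 1
        np.add.at(counts, (np.arange(lo, hi), main[lo:hi].astype(np.intp)), 1)
    if coverage.max() == 0:
        raise ValueError("no reads aligned to the consensus")
    avg = float(coverage.mean())  # before any filtering
    half = avg / 2.0
    out: list[str] = []
    kept_cov: list[int] = []
    kept_sup: list[float] = []
    for t in range(L):
        cov = int(coverage[t])
        if cov < half:
            continue  # low-coverage base removed
        col = counts[t]
        base_counts = [(int(col[i]), i) for i in range(4)]
        # tie prefers the existing consensus base, then A<C<G<T
        top_count, top_base = max(
            base_counts, key=lambda x: (x[0], x[1] == cons_codes[t], -x[1])
        )
        if int(col[GAP]) > top_count:
            continue  # majority deletion
        if top_count == 0:
            continue
        support = top_count / cov if cov else 0.0
        base = BASES[top_base]
        out.append(base if support >= 0.5 else base.lower())
        kept_cov.append(cov)
        kept_sup.append(support)
    return PolishedConsensus(
        "".join(out),
        np.asarray(kept_cov, dtype=np.int64),
        np.asarray(kept_sup),
        avg,
    )


def shortread_polish(
    consensus: str,
    merged_reads: list[str],
    unique_regions: list[tuple[int, int]],
    min_mapq: int = 20,
    min_support: float = 0.80,
    mapper: ShortReadMapper | None = None,
) -> PolishedConsensus:
    """Strict short-read substitution polish, applied only inside the
    supplied unique (non-satellite) regions.

    Alignments under ``min_mapq`` are discarded; a base is replaced when
    at least ``min_support`` of covering reads agree on a different base
    and coverage is at least half the consensus-wide average."""
    if mapper is None:
        mapper = ShortReadMapper(consensus)
    mapped = []
    for i, seq in enumerate(merged_reads):
        m = mapper.map_read(seq, f"m{i}")
        if m is not None and m.mapq >= min_mapq:
            mapped.append(m)
    L = len(consensus)
    counts, coverage = pileup(mapped, L)
    avg = float(coverage.mean())
    half = avg / 2.0
    seq = list(consensus)
    support = np.ones(L)
    in_region = np.zeros(L, dtype=bool)
    for s, e in unique_regions:
        in_region[s:e] = True
    for t in np.flatnonzero(in_region):
        cov = int(coverage[t])
        if cov == 0 or cov < half:
            continue
        col = counts[t]
        top = int(np.argmax(col[:4]))
        frac = col[top] / cov
        support[t] = frac
        if frac >= min_support:
            seq[t] = BASES[top]
    return PolishedConsensus("".join(seq), coverage, support, avg)
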