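"""Single-copy variant (satVAR) validation with short reads.

Two independent routes validate candidate variants found in a polished
clone consensus:

* k-mer route — the 21-mer spanning the variant must (1) match neither
  the cloning vector nor the canonical HOR repeat, (2) occur exactly
  once in the consensus, and (3) have a read k-mer depth inside the
  single-copy range calibrated from vector k-mers; at least two
  overlapping read k-mers must support it.
* alignment route — after mapQ filtering, at least 80% of covering
  reads must support the variant and site coverage must sit inside the
  same single-copy depth range.

The module also estimates repeat copy number from ceny/vector k-mer
depth and re-runs the false-positive and mapping simulation studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate
from .kmers import CENY, KmerLabels, KmerTable, OTHER, VECTOR, count_kmers, encode_kmer
from .mapping import ShortReadMapper, pileup, BASE_IDX
from .rngs import derive_seed, make_rng
from .seqs import encode, revcomp
from .simulate import ShortReadModel, simulate_short_reads

log = logging.getLogger(__name__)

K = 21


@dataclass
class DepthRange:
    low: int
    high: int
    quantiles: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.high:
            raise ValueError("need 0 < low <= high")

    def contains(self, depth: float) -> bool:
        return self.low <= depth <= self.high


@dataclass
class ValidationParams:
    min_support_fraction: float = 0.80
    min_mapq: int = 20
    min_overlapping_kmers: int = 2
    depth_quantiles: tuple[float, float] = (0.0, 1.0)
    k: int = K


@dataclass
class SatVar:
    """A candidate/validated single-copy repeat variant."""

    name: str
    consensus_position: int  # 0-based
    kind: str  # SUB | INS | DEL
    ref: str
    alt: str
    spanning_kmer: str = ""
    kmer_depth: int = 0
    supporting_kmer_count: int = 0
    alignment_support_fraction: float = float("nan")
    validated: bool = False
    edge: bool = False  # too close to a consensus end to evaluate


# ---------------------------------------------------------------------------
# paired-read merging


def merge_pairs(
    pairs: list[tuple[str, str, str]],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
) -> list[tuple[str, str]]:
    """Merge inward-facing mates by their best-scoring 3' overlap.

    Overlaps shorter than ``min_overlap`` or above the mismatch cap are
    not merged; unmerged mates pass through as two reads.  At conflicts
    the first mate's base is kept (constant-quality synthetic reads).
    """
    out: list[tuple[str, str]] = []
    for rid, r1, r2 in pairs:
        b = revcomp(r2)
        a1 = encode(r1)
        a2 = encode(b)
        best: tuple[int, int] | None = None  # (score, overlap)
        max_o = min(len(r1), len(b))
        for o in range(min_overlap, max_o + 1):
            mism = int((a1[-o:] != a2[:o]).sum())
            if mism <= max_mismatch_frac * o:
                score = o - 2 * mism
                if best is None or score > best[0]:
                    best = (score, o)
        if best is None:
            out.append((rid + "/1", r1))
            out.append((rid + "/2", b))
        else:
            o = best[1]
            out.append((rid, r1 + b[o:]))
    return out


# ---------------------------------------------------------------------------
# depth calibration and copy number


def vector_depth_range(
    table: KmerTable,
    labels: KmerLabels,
    quantiles: tuple[float, float] = (0.0, 1.0),
    pad: float = 0.10,
) -> DepthRange:
    """Single-copy depth range from the vector k-mer depth distribution.

    The default takes the distribution's full observed extent widened by
    ``pad`` on each side.  Adjacent vector k-mers share sequencing
    fragments, so the observed extent rests on few effectively
    independent depth draws and understates the true single-copy spread;
    the padding plays the role of reading a generous range off the
    plotted distribution, which is how worked ranges in this protocol
    relate to their vector depth extents.  Error-derived k-mers sit
    orders of magnitude below the padded lower bound, so the
    false-positive margin is unaffected."""
    lab = labels.label_all(table.kmers)
    depths = table.counts[lab == 0]
    if depths.size < 100:
        raise ValueError(f"only {depths.size} vector k-mers observed (need >= 100)")
    lo = float(np.quantile(depths, quantiles[0]))
    hi = float(np.quantile(depths, quantiles[1]))
    lo = max(1, int(np.floor(lo * (1 - pad))))
    hi = int(np.ceil(hi * (1 + pad)))
    return DepthRange(lo, hi, quantiles)


def estimate_copy_number(table: KmerTable, labels: KmerLabels) -> float:
    """HOR copy number = median ceny k-mer depth / median vector depth."""
    lab = labels.label_all(table.kmers)
    ceny = table.counts[lab == 1]
    vec = table.counts[lab == 0]
    if ceny.size == 0 or vec.size == 0:
        raise ValueError("need both ceny and vector k-mers")
    return float(np.median(ceny) / np.median(vec))


# ---------------------------------------------------------------------------
# candidate derivation


def find_candidate_variants(
    consensus: str,
    hor_reference: str,
    min_identity: float = 0.8,
    canonical_tolerance: int = 100,
) -> list[SatVar]:
    """Single-base differences between consensus HOR units and the
    canonical repeat, as candidate satVARs in consensus coordinates.

    Only length-canonical instances are scanned: structural length
    variants (and partial units truncated at consensus ends) act as
    whole-unit markers, not as bags of single-base differences."""
    cons = consensus.upper()
    instances = annotate.detect_hors(cons, hor_reference, min_identity)
    from .align import cigar_ops, global_align  # local import avoids cycle noise

    cands: list[SatVar] = []
    for h in instances:
        if abs(h.length - len(hor_reference)) > canonical_tolerance:
            continue
        unit = cons[h.start : h.end]
        aln = global_align(unit, hor_reference.upper())
        t = q = 0
        for n, op in cigar_ops(aln.cigar):
            if op in "=XM":
                if op == "X" and n == 1:
                    cands.append(
                        SatVar(
                            name=f"c{len(cands)}",
                            consensus_position=h.start + q,
                            kind="SUB",
                            ref=hor_reference[t].upper(),
                            alt=unit[q],
                        )
                    )
                t += n
                q += n
            elif op == "D":
                if n == 1:
                    cands.append(
                        SatVar(
                            name=f"c{len(cands)}",
                            consensus_position=h.start + q,
                            kind="DEL",
                            ref=hor_reference[t].upper(),
                            alt="",
                        )
                    )
                t += n
            elif op == "I":
                if n == 1:
                    cands.append(
                        SatVar(
                            name=f"c{len(cands)}",
                            consensus_position=h.start + q,
                            kind="INS",
                            ref="",
                            alt=unit[q],
                        )
                    )
                q += n
    return cands


def _spanning_window(consensus: str, pos: int, k: int) -> tuple[str, int]:
    half = k // 2
    start = min(max(pos - half, 0), len(consensus) - k)
    return consensus[start : start + k], start


def _count_in_consensus(consensus: str, kmer: str) -> int:
    n = consensus.count(kmer)
    rc = revcomp(kmer)
    if rc != kmer:
        n += consensus.count(rc)
    return n


# ---------------------------------------------------------------------------
# validation routes


def call_satvars_kmer(
    consensus: str,
    read_kmers: KmerTable,
    labels: KmerLabels,
    depth_range: DepthRange,
    params: ValidationParams | None = None,
    hor_reference: str | None = None,
    candidates: list[SatVar] | None = None,
) -> list[SatVar]:
    """k-mer route validation of candidate satVARs.

    Candidates may be supplied directly or derived from the consensus
    against ``hor_reference``.  A candidate is validated when its
    spanning 21-mer is consensus-unique, matches neither vector nor HOR
    reference, has read depth inside the single-copy range, and at
    least ``min_overlapping_kmers`` of the read k-mers overlapping the
    site fall inside that range.
    """
    p = params or ValidationParams()
    cons = consensus.upper()
    if candidates is None:
        if hor_reference is None:
            raise ValueError("need hor_reference or explicit candidates")
        candidates = find_candidate_variants(cons, hor_reference)
    k = p.k
    for v in candidates:
        pos = v.consensus_position
        if pos < k or pos > len(cons) - k:
            v.edge = True
            v.validated = False
            continue
        kmer, start = _spanning_window(cons, pos, k)
        v.spanning_kmer = kmer
        v.kmer_depth = read_kmers.get(kmer)
        if _count_in_consensus(cons, kmer) != 1:
            v.validated = False
            continue
        if labels.label(kmer) != OTHER:
            v.validated = False
            continue
        support = 0
        for ws in range(pos - k + 1, pos + 1):
            if ws < 0 or ws + k > len(cons):
                continue
            d = read_kmers.get(cons[ws : ws + k])
            if depth_range.contains(d):
                support += 1
        v.supporting_kmer_count = support
        v.validated = (
            depth_range.contains(v.kmer_depth)
            and support >= p.min_overlapping_kmers
        )
    return candidates


def validate_satvars_alignment(
    consensus: str,
    merged_reads: list[tuple[str, str]] | list[str],
    depth_range: DepthRange,
    params: ValidationParams | None = None,
    hor_reference: str | None = None,
    candidates: list[SatVar] | None = None,
    mapper: ShortReadMapper | None = None,
) -> list[SatVar]:
    """Alignment route: mapQ-filtered read support at each candidate.

    A candidate is validated when >= 80% of covering reads carry the
    variant base and coverage is inside the single-copy depth range.
    """
    p = params or ValidationParams()
    cons = consensus.upper()
    if candidates is None:
        if hor_reference is None:
            raise ValueError("need hor_reference or explicit candidates")
        candidates = find_candidate_variants(cons, hor_reference)
    if mapper is None:
        mapper = ShortReadMapper(cons)
    seqs = [r[1] if isinstance(r, tuple) else r for r in merged_reads]
    mapped = []
    for i, s in enumerate(seqs):
        m = mapper.map_read(s, f"r{i}")
        if m is not None and m.mapq >= p.min_mapq:
            mapped.append(m)
    counts, coverage = pileup(mapped, len(cons))
    for v in candidates:
        pos = v.consensus_position
        if not 0 <= pos < len(cons):
            continue
        # single-copy requirement: the variant context must be observed
        # exactly once in the consensus
        window, _ = _spanning_window(cons, pos, p.k)
        if not v.spanning_kmer:
            v.spanning_kmer = window
        if _count_in_consensus(cons, window) != 1:
            v.validated = False
            continue
        cov = int(coverage[pos])
        if v.kind == "SUB" or v.kind == "INS":
            alt_n = int(counts[pos, BASE_IDX[v.alt]]) if v.alt in BASE_IDX else 0
        else:  # DEL: support = reads agreeing with the consensus junction
            alt_n = int(counts[pos, : 4].max())
        frac = alt_n / cov if cov else 0.0
        v.alignment_support_fraction = frac
        v.validated = bool(
            cov
            and frac >= p.min_support_fraction
            and depth_range.contains(cov)
        )
    return candidates


# ---------------------------------------------------------------------------
# simulation studies


def fp_simulation(
    consensus_array: str,
    read_kmers: KmerTable,
    depth_range: DepthRange,
    trials: int = 1_000,
    params: ValidationParams | None = None,
    seed: int = 0,
) -> int:
    """False-positive study: inject one random variant per trial into a
    copy of the array and ask whether its spanning 21-mer would pass the
    depth-range criteria against reads from the *unmodified* array.
    Returns the number of (false) validations."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    p = params or ValidationParams()
    rng = make_rng(seed)
    cons = consensus_array.upper()
    k = p.k
    n_false = 0
    L = len(cons)
    for _ in range(trials):
        pos = int(rng.integers(k, L - k))
        ref = cons[pos]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(0, 4))]
        context = cons[pos - k + 1 : pos + k]
        mutated = context[: k - 1] + alt + context[k:]
        depths = [
            read_kmers.get(mutated[i : i + k]) for i in range(len(mutated) - k + 1)
        ]
        # the window centred on the variant base
        central = read_kmers.get(mutated[k // 2 : k // 2 + k])
        in_range = [d for d in depths if depth_range.contains(d)]
        if depth_range.contains(central) and len(in_range) >= p.min_overlapping_kmers:
            n_false += 1
    return n_false


def mapping_simulation(
    unit: str,
    n_copies: int = 10,
    coverage_grid: tuple[float, ...] = (100.0,),
    error_grid: tuple[float, ...] = (0.004,),
    trials: int = 100,
    params: ValidationParams | None = None,
    seed: int = 0,
    read_length: int = 250,
    fragment_mean: int = 400,
    fragment_sd: int = 40,
) -> pd.DataFrame:
    """Variant-detection study on an array of identical repeat units.

    Per trial a single random base change is introduced; paired reads
    are simulated from the variant-bearing array (and, in parallel,
    from the unmodified array) and mapped back to the variant-bearing
    reference.  A trial is a "true call" when >= 80% of mapQ-filtered
    reads covering the site support the variant and the site coverage
    reaches the validation threshold (half the nominal coverage — the
    single-copy analogue used throughout polishing).

    Only reads whose true origin can align over the variant site (i.e.
    within a read length of a position homologous to it) are mapped;
    all other reads either map elsewhere or multi-map and are removed
    by the mapQ filter, so support and coverage are unaffected.
    """
    p = params or ValidationParams()
    rows = []
    U = len(unit)
    array0 = unit.upper() * n_copies
    L = len(array0)
    for cov in coverage_grid:
        for err in error_grid:
            for trial in range(trials):
                tseed = derive_seed(seed, trial * 1_000 + int(cov) + int(err * 1e6))
                rng = make_rng(tseed)
                vpos = int(rng.integers(0, L))
                ref_base = array0[vpos]
                alt = "ACGT"[int(rng.integers(0, 4))]
                while alt == ref_base:
                    alt = "ACGT"[int(rng.integers(0, 4))]
                ref_var = array0[:vpos] + alt + array0[vpos + 1 :]
                mapper = ShortReadMapper(ref_var)
                voff = vpos % U
                model = ShortReadModel(
                    read_length=read_length,
                    fragment_mean=fragment_mean,
                    fragment_sd=fragment_sd,
                    substitution_rate=err,
                    coverage=cov,
                )
                for label, source in (("variant", ref_var), ("novariant", array0)):
                    pairs, origins = simulate_short_reads(
                        source, model, seed=derive_seed(tseed, 1 if label == "variant" else 2)
                    )
                    reads = _reads_over_homologous_site(
                        pairs, origins, voff, U, L, read_length
                    )
                    mapped = []
                    for i, s in enumerate(reads):
                        m = mapper.map_read(s, f"r{i}")
                        if m is not None and m.mapq >= p.min_mapq:
                            mapped.append(m)
                    counts, coverage = pileup(mapped, L)
                    site_cov = int(coverage[vpos])
                    alt_n = int(counts[vpos, BASE_IDX[alt]])
                    support = alt_n / site_cov if site_cov else 0.0
                    cov_ok = site_cov >= cov / 2
                    rows.append(
                        {
                            "coverage": cov,
                            "error_rate": err,
                            "trial": trial,
                            "read_set": label,
                            "site_coverage": site_cov,
                            "support": support,
                            "coverage_ok": cov_ok,
                            "true_call": bool(
                                cov_ok and support >= p.min_support_fraction
                            ),
                        }
                    )
    return pd.DataFrame(rows)


def polishing_simulation(
    length: int = 73_000,
    coverage: float = 30.0,
    seed: int = 0,
    draft_sub_rate: float = 0.01,
    draft_indel_rate: float = 0.001,
    min_support: float = 0.80,
    min_mapq: int = 20,
    read_length: int = 250,
    fragment_mean: int = 400,
) -> dict:
    """Short-read polishing study on a unique control sequence.

    A draft carrying known errors (substitutions plus a small indel
    load, emulating a long-read consensus) is polished with simulated
    paired reads from the true sequence under the mapQ >= 20 and 80%-
    support substitution rules; reports draft and polished identity to
    the truth (global-alignment identity).
    """
    from .align import identity
    from .consensus import shortread_polish
    from .seqs import mutate, random_seq

    rng = make_rng(derive_seed(seed, 73))
    truth_seq = random_seq(length, rng)
    draft = mutate(truth_seq, rng, sub_rate=draft_sub_rate,
                   indel_rate=draft_indel_rate)
    model = ShortReadModel(
        read_length=read_length,
        fragment_mean=fragment_mean,
        substitution_rate=0.004,
        coverage=coverage,
    )
    pairs, _ = simulate_short_reads(truth_seq, model, seed=derive_seed(seed, 74))
    merged = [s for _, s in merge_pairs(pairs)]
    pol = shortread_polish(
        draft, merged, [(0, len(draft))],
        min_mapq=min_mapq, min_support=min_support,
    )
    return {
        "draft_identity": identity(draft, truth_seq),
        "polished_identity": identity(pol.sequence.upper(), truth_seq),
        "coverage": coverage,
        "length": length,
    }


def _reads_over_homologous_site(
    pairs, origins, voff: int, unit_len: int, array_len: int, read_length: int
) -> list[str]:
    """Mates whose true interval covers a position homologous to the
    variant offset (mod unit length)."""
    out = []
    for rid, r1, r2 in pairs:
        o = origins[rid]
        s1 = o.start
        s2 = o.start + o.length - read_length
        if (voff - s1) % unit_len < read_length:
            out.append(r1)
        if (voff - s2) % unit_len < read_length:
            out.append(revcomp(r2))
    return out
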