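"""Synthetic satellite-array data with planted ground truth.

Generates the full study geometry end to end: a higher-order-repeat
(HOR) array with rare single-copy variants, structural length variants
and haplotype blocks, flanked by divergent monomeric satellite and
unique arm sequence; circular vector+insert BAC constructs tiling the
locus; nanopore-like long reads (i.i.d. errors with a homopolymer indel
bias, random circular cut point, both strands); MiSeq-like paired short
reads with substitution errors; and ChIP/background read sets enriched
over the array.

Every operation is deterministic given its seed, and every emitted read
carries an origin record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rngs import derive_seed, make_rng
from .seqs import decode, encode, mutate, random_seq, revcomp, rotate

KMER_K = 21  # spanning k-mer size used for variant truth/uniqueness

# ---------------------------------------------------------------------------
# specs and truth records


@dataclass
class ArraySpec:
    """Parametric description of a planted HOR array locus.

    ``haplotype_block_layout`` labels are bit-strings over
    ``haplotype_sites`` ('1' = the block's HORs carry the alternate base
    at that site); blocks are 0-based half-open over HOR indices and
    must tile [0, hor_count).
    """

    monomer_length: int = 200
    monomers_per_hor: int = 6
    hor_count: int = 20
    structural_variants: list[tuple[int, int]] = field(default_factory=list)
    single_copy_variants: list[tuple[int, int, str, str]] = field(default_factory=list)
    haplotype_sites: list[tuple[int, str]] = field(default_factory=list)
    haplotype_block_layout: list[tuple[int, int, str]] = field(default_factory=list)
    flank_monomeric: int = 2_000
    flank_arm: int = 6_000
    flank_divergence: float = 0.20
    seed: int = 0

    @property
    def unit_length(self) -> int:
        return self.monomer_length * self.monomers_per_hor

    def __post_init__(self) -> None:
        if self.hor_count < 1:
            raise ValueError("hor_count must be >= 1")
        keys = [(h, o) for h, o, _, _ in self.single_copy_variants]
        if len(set(keys)) != len(keys):
            raise ValueError("single_copy_variants must have unique (hor, offset)")
        for h, _ in self.structural_variants:
            if not 0 <= h < self.hor_count:
                raise ValueError(f"structural variant index {h} out of range")
        for h, o, kind, _ in self.single_copy_variants:
            if not 0 <= h < self.hor_count:
                raise ValueError(f"variant HOR index {h} out of range")
            if not 0 <= o < self.unit_length:
                raise ValueError(f"variant offset {o} outside HOR unit")
            if kind not in ("SUB", "INS", "DEL"):
                raise ValueError(f"unknown variant kind {kind!r}")
        if self.haplotype_block_layout:
            blocks = sorted(self.haplotype_block_layout)
            cursor = 0
            for start, end, label in blocks:
                if start != cursor or end <= start:
                    raise ValueError("haplotype blocks must tile [0, hor_count)")
                if len(label) != len(self.haplotype_sites):
                    raise ValueError("block label length != number of haplotype sites")
                cursor = end
            if cursor != self.hor_count:
                raise ValueError("haplotype blocks must tile [0, hor_count)")


@dataclass
class BACSpec:
    """One circular vector+insert clone over the locus coordinate system."""

    name: str
    vector_sequence: str
    insert_interval: tuple[int, int]  # 0-based half-open on the locus
    orientation: str = "+"

    def __post_init__(self) -> None:
        if len(self.vector_sequence) <= 3_000:
            raise ValueError("vector must be > 3 kb for anchor detection")
        s, e = self.insert_interval
        if not 0 <= s < e:
            raise ValueError("invalid insert interval")
        if self.orientation not in "+-":
            raise ValueError("orientation must be + or -")


@dataclass
class LongReadModel:
    """Outcome-level nanopore read model (identity, error mix, strands)."""

    median_identity: float = 0.848
    error_mix: tuple[float, float, float] = (0.40, 0.30, 0.30)  # mis, ins, del
    homopolymer_bias: float = 2.0
    full_length_fraction: float = 0.5
    truncation_range: tuple[float, float] = (0.1, 0.9)
    strand_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.median_identity < 1:
            raise ValueError("median_identity must be in (0, 1)")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must sum to 1")
        if self.homopolymer_bias < 1:
            raise ValueError("homopolymer_bias must be >= 1")

    @property
    def per_base_error(self) -> float:
        """Per-true-base error rate that realizes the target alignment identity.

        With mismatch/insertion/deletion fractions (m, i, d) and error
        rate e, identity = (1 - e(m+d)) / (1 + e*i); invert for e.
        """
        m, i, d = self.error_mix
        target = self.median_identity
        return (1.0 - target) / (m + d + target * i)


@dataclass
class ShortReadModel:
    """MiSeq-like paired-end model: fixed read length, Gaussian fragments,
    i.i.d. substitution errors."""

    read_length: int = 250
    fragment_mean: int = 400
    fragment_sd: int = 40
    substitution_rate: float = 0.004
    coverage: float = 100.0
    seed: int = 0


@dataclass
class PlantedVariant:
    """Truth record for one planted single-copy variant."""

    name: str
    hor_index: int
    unit_offset: int
    locus_pos: int
    kind: str
    ref: str
    alt: str
    spanning_kmer: str


@dataclass
class ReadOrigin:
    start: int
    length: int
    strand: str
    full_length: bool = False


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted locus."""

    locus_sequence: str
    hor_intervals: list[tuple[int, int, str]]  # (start, end, class)
    planted_variants: list[PlantedVariant]
    hor_haplotypes: list[str]
    canonical_unit: str
    monomer: str
    array_interval: tuple[int, int]
    monomeric_intervals: list[tuple[int, int]]
    bac_order: list[str] = field(default_factory=list)
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)


@dataclass
class BACConstruct:
    name: str
    sequence: str  # rotationally arbitrary circular sequence
    vector_sequence: str
    insert_interval: tuple[int, int]
    orientation: str
    insert_sequence: str  # forward-locus-frame insert, for truth checks


# ---------------------------------------------------------------------------
# array construction

_INTRA_UNIT_DIVERGENCE = 0.20  # monomer-to-monomer divergence within one HOR


def _spanning_kmer(locus: str, pos: int, k: int = KMER_K) -> str:
    half = k // 2
    start = min(max(pos - half, 0), len(locus) - k)
    return locus[start : start + k]


def _canonical_count(locus: str, kmer: str) -> int:
    """Occurrences of a k-mer in the locus counting both orientations."""
    n = locus.count(kmer)
    rc = revcomp(kmer)
    if rc != kmer:
        n += locus.count(rc)
    return n


def _build_unit(
    spec: ArraySpec,
    hor_index: int,
    canonical_unit: str,
    structural_blocks: dict[int, str],
    block_labels: list[str],
) -> tuple[str, str, list[tuple[int, int]]]:
    """Assemble one HOR unit; returns (sequence, class, unit-frame edits).

    Edits are applied from highest canonical offset downward so that
    earlier offsets stay valid; the returned edit list maps canonical
    offsets to offsets within the emitted unit for truth bookkeeping.
    """
    edits: list[tuple[int, str, str, str]] = []  # (offset, kind, ref, alt)
    label = block_labels[hor_index] if block_labels else ""
    for site_i, (off, alt) in enumerate(spec.haplotype_sites):
        if label and label[site_i] == "1":
            edits.append((off, "HAP", canonical_unit[off], alt))
    struct_delta = dict(spec.structural_variants).get(hor_index)
    ins_off = (spec.monomers_per_hor // 2) * spec.monomer_length
    if struct_delta is not None:
        edits.append((ins_off, "STRUCT", "", structural_blocks[struct_delta]))
    for h, off, kind, alt in spec.single_copy_variants:
        if h != hor_index:
            continue
        if any(off == e[0] for e in edits):
            raise ValueError(
                f"variant at HOR {h} offset {off} collides with another edit"
            )
        ref = canonical_unit[off] if kind != "INS" else ""
        edits.append((off, kind, ref, alt if kind != "DEL" else ""))

    # apply high-to-low so earlier canonical offsets stay valid
    seq = canonical_unit
    for off, kind, ref, alt in sorted(edits, reverse=True):
        if kind in ("HAP", "SUB"):
            seq = seq[:off] + alt + seq[off + 1 :]
        elif kind == "INS":
            seq = seq[:off] + alt + seq[off:]
        elif kind == "DEL":
            seq = seq[:off] + seq[off + 1 :]
        else:  # STRUCT insertion block
            seq = seq[:off] + alt + seq[off:]
    unit_class = "structural" if struct_delta is not None else "canonical"
    # an edit's emitted offset = canonical offset + net length change of
    # all edits strictly before it
    offmap = []
    for off, kind, ref, alt in edits:
        shift = 0
        for o2, kind2, _, alt2 in edits:
            if o2 < off:
                if kind2 in ("INS", "STRUCT"):
                    shift += len(alt2)
                elif kind2 == "DEL":
                    shift -= 1
        offmap.append((off, off + shift))
    return seq, unit_class, offmap


def _block_labels(spec: ArraySpec) -> list[str]:
    if not spec.haplotype_block_layout:
        return ["0" * len(spec.haplotype_sites)] * spec.hor_count
    labels = [""] * spec.hor_count
    for start, end, label in spec.haplotype_block_layout:
        for i in range(start, end):
            labels[i] = label
    return labels


def make_array(spec: ArraySpec) -> tuple[str, GroundTruth]:
    """Build the locus (flank + HOR array + flank) and its ground truth.

    Regenerates with a derived seed until every planted single-copy
    variant's spanning 21-mer occurs exactly once in the locus (both
    orientations counted).
    """
    for attempt in range(25):
        locus, truth = _make_array_once(spec, derive_seed(spec.seed, attempt))
        kmers = [v.spanning_kmer for v in truth.planted_variants]
        if len(set(kmers)) == len(kmers) and all(
            _canonical_count(locus, k) == 1 for k in kmers
        ):
            return locus, truth
    raise RuntimeError("could not generate a locus with unique variant k-mers")


def _next_base(b: str) -> str:
    return "ACGT"[("ACGT".index(b) + 1) % 4]


def _make_array_once(spec: ArraySpec, seed: int) -> tuple[str, GroundTruth]:
    rng = make_rng(seed)
    monomer = random_seq(spec.monomer_length, rng)
    canonical_unit = "".join(
        mutate(monomer, rng, sub_rate=_INTRA_UNIT_DIVERGENCE)
        for _ in range(spec.monomers_per_hor)
    )
    # substitution alleles must actually differ from the canonical base
    spec = replace(
        spec,
        haplotype_sites=[
            (off, _next_base(alt) if canonical_unit[off] == alt else alt)
            for off, alt in spec.haplotype_sites
        ],
        single_copy_variants=[
            (h, off, kind,
             _next_base(alt) if kind == "SUB" and canonical_unit[off] == alt else alt)
            for h, off, kind, alt in spec.single_copy_variants
        ],
    )
    # one shared insert block per distinct length delta (the array's
    # structural variant is a single repeated type); random content —
    # unrelated to the monomer — keeps unit junctions unambiguous
    structural_blocks: dict[int, str] = {}
    for _, delta in spec.structural_variants:
        if delta not in structural_blocks:
            structural_blocks[delta] = random_seq(delta, rng)

    def monomeric_flank() -> str:
        ncopies = spec.flank_monomeric // spec.monomer_length + 1
        seq = "".join(
            mutate(monomer, rng, sub_rate=spec.flank_divergence,
                   indel_rate=spec.flank_divergence / 10)
            for _ in range(ncopies)
        )
        return seq[: spec.flank_monomeric]

    left_arm = random_seq(spec.flank_arm, rng)
    right_arm = random_seq(spec.flank_arm, rng)
    left_mono = monomeric_flank()
    right_mono = monomeric_flank()

    labels = _block_labels(spec)
    parts = [left_arm, left_mono]
    pos = spec.flank_arm + spec.flank_monomeric
    array_start = pos
    hor_intervals: list[tuple[int, int, str]] = []
    variant_records: list[PlantedVariant] = []
    single_by_unit: dict[int, list[tuple[int, str, str]]] = {}
    for h, off, kind, alt in spec.single_copy_variants:
        single_by_unit.setdefault(h, []).append((off, kind, alt))
    for i in range(spec.hor_count):
        seq, unit_class, offmap = _build_unit(
            spec, i, canonical_unit, structural_blocks, labels
        )
        hor_intervals.append((pos, pos + len(seq), unit_class))
        emitted_of = dict(offmap)
        for off, kind, alt in single_by_unit.get(i, []):
            ref = canonical_unit[off] if kind != "INS" else ""
            variant_records.append(
                PlantedVariant(
                    name=f"v{len(variant_records)}",
                    hor_index=i,
                    unit_offset=off,
                    locus_pos=pos + emitted_of[off],
                    kind=kind,
                    ref=ref,
                    alt=alt if kind != "DEL" else "",
                    spanning_kmer="",
                )
            )
        parts.append(seq)
        pos += len(seq)
    array_end = pos
    parts.extend([right_mono, right_arm])
    locus = "".join(parts)
    for v in variant_records:
        v.spanning_kmer = _spanning_kmer(locus, v.locus_pos)
    truth = GroundTruth(
        locus_sequence=locus,
        hor_intervals=hor_intervals,
        planted_variants=variant_records,
        hor_haplotypes=labels,
        canonical_unit=canonical_unit,
        monomer=monomer,
        array_interval=(array_start, array_end),
        monomeric_intervals=[
            (spec.flank_arm, spec.flank_arm + spec.flank_monomeric),
            (array_end, array_end + spec.flank_monomeric),
        ],
    )
    return locus, truth


# ---------------------------------------------------------------------------
# BAC constructs


def make_bacs(
    locus: str,
    tiling: list[BACSpec],
    truth: GroundTruth,
    seed: int = 0,
) -> list[BACConstruct]:
    """Cut the locus into circular vector+insert constructs.

    Adjacent clones (by insert start) must overlap and share at least
    one planted single-copy variant or a stretch of non-array (anchor)
    sequence; otherwise ordering evidence cannot exist and the tiling
    is rejected.  Records the true p->q clone order in ``truth``.
    """
    rng = make_rng(seed)
    ordered = sorted(tiling, key=lambda b: b.insert_interval[0])
    arr_s, arr_e = truth.array_interval
    for a, b in zip(ordered, ordered[1:]):
        ov_s = max(a.insert_interval[0], b.insert_interval[0])
        ov_e = min(a.insert_interval[1], b.insert_interval[1])
        if ov_e <= ov_s:
            raise ValueError(f"tiling gap between {a.name} and {b.name}")
        has_var = any(
            ov_s <= v.locus_pos < ov_e for v in truth.planted_variants
        )
        has_anchor = ov_s < arr_s or ov_e > arr_e
        if not (has_var or has_anchor):
            raise ValueError(
                f"overlap between {a.name} and {b.name} carries no planted "
                "variant and no arm anchor"
            )
    constructs = []
    for spec in ordered:
        s, e = spec.insert_interval
        if e > len(locus):
            raise ValueError(f"{spec.name}: insert interval outside locus")
        insert = locus[s:e]
        oriented = insert if spec.orientation == "+" else revcomp(insert)
        circ = spec.vector_sequence + oriented
        rot = int(rng.integers(0, len(circ)))
        constructs.append(
            BACConstruct(
                name=spec.name,
                sequence=rotate(circ, rot),
                vector_sequence=spec.vector_sequence,
                insert_interval=(s, e),
                orientation=spec.orientation,
                insert_sequence=insert,
            )
        )
    truth.bac_order = [c.name for c in constructs]
    return constructs


# ---------------------------------------------------------------------------
# long reads


def _homopolymer_mask(codes: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs >= min_run."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = codes[1:] != codes[:-1]
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def apply_read_errors(
    seq: str, model: LongReadModel, rng: np.random.Generator
) -> str:
    """i.i.d. per-base mismatch/ins/del errors with a homopolymer
    multiplier on indel rates."""
    codes = encode(seq)
    n = codes.size
    e = model.per_base_error
    f_mis, f_ins, f_del = model.error_mix
    hp = _homopolymer_mask(codes)
    bias = np.where(hp, model.homopolymer_bias, 1.0)
    p_mis = np.full(n, e * f_mis)
    p_ins = e * f_ins * bias
    p_del = e * f_del * bias
    total = p_mis + p_ins + p_del
    over = total > 0.95
    if over.any():  # keep probabilities valid under extreme bias
        scale = 0.95 / total[over]
        p_mis[over] *= scale
        p_ins[over] *= scale
        p_del[over] *= scale
    draw = rng.random(n)
    del_mask = draw < p_del
    mis_mask = (draw >= p_del) & (draw < p_del + p_mis)
    ins_mask = (draw >= p_del + p_mis) & (draw < p_del + p_mis + p_ins)
    out = codes.copy()
    n_mis = int(mis_mask.sum())
    if n_mis:
        out[mis_mask] = (out[mis_mask] + rng.integers(1, 4, n_mis)) % 4
    reps = (~del_mask).astype(np.intp) + ins_mask.astype(np.intp)
    result = np.repeat(out, reps)
    if ins_mask.any():
        # the duplicated slot (second copy) becomes a random inserted base
        ends = np.cumsum(reps)
        ins_slots = ends[ins_mask & ~del_mask] - 1
        result[ins_slots] = rng.integers(0, 4, ins_slots.size)
    return decode(result)


def simulate_long_reads(
    construct: BACConstruct | str,
    model: LongReadModel,
    n: int,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], dict[str, ReadOrigin]]:
    """Nanopore-like reads of a circular construct.

    A ``full_length_fraction`` of reads traverse the whole circle from a
    uniform cut point; the rest are prefix truncations.  Strands are
    balanced; errors follow the model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = construct.sequence if isinstance(construct, BACConstruct) else construct
    name = construct.name if isinstance(construct, BACConstruct) else "seq"
    rng = make_rng(model.seed if seed is None else seed)
    L = len(seq)
    reads: list[tuple[str, str]] = []
    origins: dict[str, ReadOrigin] = {}
    lo, hi = model.truncation_range
    for i in range(n):
        cut = int(rng.integers(0, L))
        full = bool(rng.random() < model.full_length_fraction)
        true = rotate(seq, cut)
        if not full:
            true = true[: max(50, int(rng.uniform(lo, hi) * L))]
        strand = "-" if rng.random() < model.strand_prob else "+"
        observed = apply_read_errors(true, model, rng)
        if strand == "-":
            observed = revcomp(observed)
        rid = f"{name}_read{i:05d}"
        reads.append((rid, observed))
        origins[rid] = ReadOrigin(cut, len(true), strand, full)
    return reads, origins


# ---------------------------------------------------------------------------
# short reads


def _extract_pairs(
    codes: np.ndarray,
    starts: np.ndarray,
    frags: np.ndarray,
    read_length: int,
    sub_rate: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    n = starts.size
    rl = read_length
    idx1 = starts[:, None] + np.arange(rl)[None, :]
    r1 = codes[idx1]
    idx2 = (starts + frags - 1)[:, None] - np.arange(rl)[None, :]
    r2 = 3 - codes[idx2]  # reverse complement of fragment 3' end
    if sub_rate > 0:
        for mat in (r1, r2):
            hit = rng.random(mat.shape) < sub_rate
            nh = int(hit.sum())
            if nh:
                mat[hit] = (mat[hit] + rng.integers(1, 4, nh)) % 4
    return [decode(row) for row in r1], [decode(row) for row in r2]


def simulate_short_reads(
    sequence: str,
    model: ShortReadModel,
    seed: int | None = None,
    circular: bool = False,
) -> tuple[list[tuple[str, str, str]], dict[str, ReadOrigin]]:
    """Inward-facing paired reads at the model's coverage.

    Pair count = coverage * len / (2 * read_length).  Fragment lengths
    are Gaussian; draws shorter than the read length are resampled.
    ``circular`` treats the template as a circle (clone resequencing),
    removing the coverage ramp at linear sequence ends.
    Returns (id, R1, R2) triples plus per-pair origins.
    """
    L = len(sequence)
    if L <= model.fragment_mean:
        raise ValueError("sequence shorter than mean fragment")
    rng = make_rng(model.seed if seed is None else seed)
    n_pairs = int(round(model.coverage * L / (2 * model.read_length)))
    frags = np.rint(
        rng.normal(model.fragment_mean, model.fragment_sd, n_pairs)
    ).astype(np.intp)
    bad = frags < model.read_length
    while bad.any():  # resample rather than truncate (documented contract)
        frags[bad] = np.rint(
            rng.normal(model.fragment_mean, model.fragment_sd, int(bad.sum()))
        ).astype(np.intp)
        bad = frags < model.read_length
    frags = np.minimum(frags, L)
    if circular:
        starts = (rng.random(n_pairs) * L).astype(np.intp)
        codes = encode(sequence + sequence[: int(frags.max())])
    else:
        starts = (rng.random(n_pairs) * (L - frags + 1)).astype(np.intp)
        codes = encode(sequence)
    r1s, r2s = _extract_pairs(
        codes, starts, frags, model.read_length, model.substitution_rate, rng
    )
    pairs = []
    origins: dict[str, ReadOrigin] = {}
    for i, (a, b) in enumerate(zip(r1s, r2s)):
        rid = f"pair{i:06d}"
        pairs.append((rid, a, b))
        origins[rid] = ReadOrigin(int(starts[i]), int(frags[i]), "+", False)
    return pairs, origins


def simulate_chip(
    locus: str,
    truth: GroundTruth,
    enrichment_fold: float,
    model: ShortReadModel,
    seed: int | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """ChIP and background paired read sets.

    ChIP fragment starts are drawn with weight ``enrichment_fold``
    inside the HOR array and 1 outside; the background is uniform.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    rng = make_rng(model.seed if seed is None else seed)
    L = len(locus)
    codes = encode(locus)
    n_pairs = int(round(model.coverage * L / (2 * model.read_length)))
    arr_s, arr_e = truth.array_interval
    frag = model.fragment_mean

    def draw(weighted: bool) -> tuple[np.ndarray, np.ndarray]:
        max_start = L - frag
        w = np.ones(max_start + 1)
        if weighted:
            mid_in = (np.arange(max_start + 1) + frag // 2 >= arr_s) & (
                np.arange(max_start + 1) + frag // 2 < arr_e
            )
            w[mid_in] = enrichment_fold
        w /= w.sum()
        starts = rng.choice(max_start + 1, size=n_pairs, p=w).astype(np.intp)
        frags = np.full(n_pairs, frag, dtype=np.intp)
        return starts, frags

    out = []
    for tag, weighted in (("chip", True), ("bg", False)):
        starts, frags = draw(weighted)
        r1s, r2s = _extract_pairs(
            codes, starts, frags, model.read_length, model.substitution_rate, rng
        )
        out.append(
            [(f"{tag}{i:06d}", a, b) for i, (a, b) in enumerate(zip(r1s, r2s))]
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# canned geometries


def scaled_spec(seed: int = 0) -> ArraySpec:
    """Desk-scale default geometry: 1.2 kb HORs (200 bp x 6), 20 units,
    two structural-variant clusters, haplotype blocks, and a spread of
    single-copy variants."""
    return ArraySpec(
        monomer_length=200,
        monomers_per_hor=6,
        hor_count=20,
        structural_variants=[(4, 240), (5, 240), (14, 240)],
        single_copy_variants=[
            (1, 351, "SUB", "A"),
            (3, 777, "SUB", "C"),
            (6, 523, "DEL", ""),
            (8, 912, "SUB", "G"),
            (10, 141, "INS", "T"),
            (12, 660, "SUB", "T"),
            (15, 433, "SUB", "A"),
            (17, 1_020, "SUB", "C"),
            (18, 245, "SUB", "G"),
        ],
        haplotype_sites=[(101, "A"), (404, "C"), (707, "G"), (1_111, "T")],
        haplotype_block_layout=[
            (0, 7, "0000"),
            (7, 13, "1011"),
            (13, 20, "0110"),
        ],
        seed=seed,
    )


def full_scale_spec(seed: int = 0) -> ArraySpec:
    """Geometry matching the real Y-centromere study: ~5.8 kb HORs
    (171 bp x 34), 52 copies, 7 structural variants in two clusters."""
    return ArraySpec(
        monomer_length=171,
        monomers_per_hor=34,
        hor_count=52,
        structural_variants=[(10, 230), (11, 230), (12, 230), (13, 230),
                             (40, 230), (41, 230), (42, 230)],
        single_copy_variants=[
            (i, 200 + (337 * i) % 5_500, "SUB", "ACGT"[i % 4])
            for i in range(0, 52, 4)
        ],
        flank_monomeric=20_000,
        flank_arm=12_000,
        seed=seed,
    )


def default_vector(seed: int = 97, length: int = 4_000) -> str:
    """Synthetic stand-in cloning vector (the real one is ~11.5 kb;
    anything > 3 kb satisfies anchor detection)."""
    return random_seq(length, make_rng(seed))


def scaled_tiling(
    truth: GroundTruth,
    n_bacs: int = 3,
    vector: str | None = None,
    overlap_halfwidth: int = 1_200,
) -> list[BACSpec]:
    """Clone tiling across the locus, p-arm to q-arm.

    Overlaps are centred on planted single-copy variants (the panel is
    chosen so every clone junction is informative, as a real clone
    tiling path would be); with more clones than variants the tiling
    falls back to even spacing.
    """
    vec = vector if vector is not None else default_vector()
    L = len(truth.locus_sequence)
    if n_bacs == 1:
        return [BACSpec("bac00", vec, (0, L))]
    variants = sorted(v.locus_pos for v in truth.planted_variants)
    if len(variants) >= n_bacs - 1:
        idx = np.round(
            np.linspace(0, len(variants) - 1, n_bacs + 1)
        ).astype(int)[1:-1]
        for i in range(1, idx.size):  # keep indices strictly increasing
            idx[i] = max(idx[i], idx[i - 1] + 1)
        centers = [variants[i] for i in idx]
        bounds = [0, *centers, L]
        specs = []
        for i in range(n_bacs):
            s = max(0, bounds[i] - (overlap_halfwidth if i else 0))
            e = min(L, bounds[i + 1] + (overlap_halfwidth if i + 1 < n_bacs else 0))
            specs.append(BACSpec(f"bac{i:02d}", vec, (s, e)))
        return specs
    span = L / (n_bacs + 1)
    specs = []
    for i in range(n_bacs):
        s = int(i * span)
        e = int(min(L, (i + 2) * span))
        specs.append(BACSpec(f"bac{i:02d}", vec, (s, e)))
    specs[-1] = replace(specs[-1], insert_interval=(specs[-1].insert_interval[0], L))
    return specs
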