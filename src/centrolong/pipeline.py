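"""End-to-end orchestration of the clone assembly pipeline.

A ``RunConfig`` fully determines a run: one master seed is expanded
into fixed per-stage seeds, so re-running an identical config yields
byte-identical artifacts.  Stages: simulate (synthetic mode) ->
select -> consensus -> polish -> validate -> annotate -> assemble ->
(optional) enrich, each persisting its outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate, assemble, io
from .align import infix_align
from .consensus import (
    ConsensusParams,
    SamplePlan,
    iterate_consensus,
    polish,
    shortread_polish,
)
from .kmers import build_labels, count_kmers
from .rngs import derive_seed
from .select import SelectionParams, select_full_length
from .simulate import (
    ArraySpec,
    LongReadModel,
    ShortReadModel,
    default_vector,
    make_array,
    make_bacs,
    scaled_spec,
    scaled_tiling,
    simulate_chip,
    simulate_long_reads,
    simulate_short_reads,
)
from .validate import (
    ValidationParams,
    call_satvars_kmer,
    find_candidate_variants,
    merge_pairs,
    validate_satvars_alignment,
    vector_depth_range,
)

log = logging.getLogger(__name__)

_STAGE_OFFSETS = {
    "array": 1,
    "bacs": 2,
    "chip": 3,
    "longreads": 100,
    "shortreads": 200,
    "consensus": 300,
}


@dataclass
class RunConfig:
    """Whole-pipeline configuration (synthetic mode)."""

    seed: int
    outdir: str
    n_bacs: int = 3
    long_reads_per_bac: int = 400
    long_read_identity: float = 0.848
    full_length_fraction: float = 0.5
    short_read_coverage: float = 100.0
    reads_per_sample: int = 60
    iterations: int = 10
    run_enrichment: bool = False
    enrichment_fold: float = 5.5
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ValueError("config must provide a seed")
        if "outdir" not in d:
            raise ValueError("config must provide an outdir")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def trim_vector(consensus: str, vector: str, anchor: int = 3_000) -> str:
    """Drop the trailing vector portion of a forward-frame consensus."""
    head = vector[: min(anchor, len(vector))]
    aln = infix_align(head, consensus)
    if aln is None or aln.edit_distance > 0.45 * len(head):
        return consensus
    return consensus[: aln.target_start]


def run_pipeline(config: RunConfig):
    """Execute the full synthetic-mode pipeline; returns the assembly
    and a per-stage report dict.  Logs every threshold applied."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    report: dict = {}

    # --- simulate ---------------------------------------------------------
    spec = scaled_spec(seed=derive_seed(seed, _STAGE_OFFSETS["array"]))
    locus, truth = make_array(spec)
    vector = default_vector()
    tiling = scaled_tiling(truth, n_bacs=config.n_bacs, vector=vector)
    bacs = make_bacs(locus, tiling, truth, seed=derive_seed(seed, _STAGE_OFFSETS["bacs"]))
    io.write_fasta(out / "locus.fa", [("locus", locus)])
    io.write_fasta(out / "vector.fa", [("vector", vector)])
    io.write_fasta(out / "hor_reference.fa", [("hor_ref", truth.canonical_unit)])
    io.write_bed(
        out / "truth_hors.bed",
        [(s, e, cls) for s, e, cls in truth.hor_intervals],
        chrom="locus",
    )
    report["locus_length"] = len(locus)
    report["true_bac_order"] = list(truth.bac_order)

    lr_model = LongReadModel(
        median_identity=config.long_read_identity,
        full_length_fraction=config.full_length_fraction,
    )
    sr_model = ShortReadModel(coverage=config.short_read_coverage)
    p_anchor = locus[: spec.flank_arm]
    q_anchor = locus[-spec.flank_arm :]

    consensuses: dict[str, str] = {}
    satvar_sets: dict[str, list] = {}
    for i, bac in enumerate(bacs):
        log.info("[%s] simulating reads", bac.name)
        long_reads, _ = simulate_long_reads(
            bac, lr_model, config.long_reads_per_bac,
            seed=derive_seed(seed, _STAGE_OFFSETS["longreads"] + i),
        )
        pairs, _ = simulate_short_reads(
            bac.sequence, sr_model, circular=True,
            seed=derive_seed(seed, _STAGE_OFFSETS["shortreads"] + i),
        )
        # --- select ------------------------------------------------------
        log.info("[%s] selecting full-length reads (>=3 kb vector rule)", bac.name)
        selected = select_full_length(long_reads, vector, SelectionParams())
        report[f"{bac.name}_selected"] = len(selected)
        if len(selected) < 2:
            raise RuntimeError(f"stage select failed for {bac.name}: <2 full-length reads")
        # --- consensus + polish -------------------------------------------
        log.info(
            "[%s] consensus: %d reads x %d iterations, gap rule <10",
            bac.name, config.reads_per_sample, config.iterations,
        )
        plan = SamplePlan(
            reads_per_sample=config.reads_per_sample,
            iterations=config.iterations,
            seed=derive_seed(seed, _STAGE_OFFSETS["consensus"] + i),
        )
        forward = [s.forward_sequence for s in selected]
        meta = iterate_consensus(forward, plan, ConsensusParams())
        polished = polish(meta, forward)
        cons = trim_vector(polished.sequence.upper(), vector)
        # short-read polish on unique (non-satellite) regions
        merged = merge_pairs(pairs)
        instances = annotate.detect_hors(cons, truth.canonical_unit)
        unique_regions = _non_satellite_regions(cons, instances, truth.monomer)
        log.info("[%s] short-read polish: mapQ>=20, support>=0.80", bac.name)
        sr_pol = shortread_polish(cons, [s for _, s in merged], unique_regions)
        cons = sr_pol.sequence.upper()
        consensuses[bac.name] = cons
        io.write_fasta(out / f"{bac.name}_consensus.fa", [(bac.name, cons)])
        # --- validate ------------------------------------------------------
        log.info("[%s] satVAR validation: k=21, >=2 overlapping k-mers", bac.name)
        table = count_kmers([s for _, s in merged], k=21, source=bac.name)
        labels = build_labels(vector, truth.canonical_unit, k=21)
        depth_range = vector_depth_range(table, labels)
        cands = find_candidate_variants(cons, truth.canonical_unit)
        call_satvars_kmer(
            cons, table, labels, depth_range,
            ValidationParams(), candidates=cands,
        )
        kmer_valid = {v.name for v in cands if v.validated}
        validate_satvars_alignment(
            cons, [s for _, s in merged], depth_range,
            ValidationParams(), candidates=cands,
        )
        for v in cands:  # either route validates (k-mer OR alignment)
            v.validated = v.validated or v.name in kmer_valid
        satvars = [v for v in cands if v.validated]
        satvar_sets[bac.name] = satvars
        io.write_satvars(out / f"{bac.name}_satvars.tsv", cands)
        report[f"{bac.name}_satvars"] = len(satvars)

    # --- assemble ----------------------------------------------------------
    log.info("assembling %d clones from shared satVARs + arm anchors", len(bacs))
    evidence = assemble.find_overlaps(satvar_sets)
    anchors = assemble.anchor_arms(consensuses, p_anchor, q_anchor)
    asm = assemble.order_and_merge(
        consensuses, evidence, anchors,
        hor_reference=truth.canonical_unit,
        monomer_reference=truth.monomer,
    )
    io.write_fasta(out / "assembly.fa", [("assembly", asm.sequence)])
    report["assembly_order"] = asm.order
    report["hor_count"] = asm.hor_count
    report["array_length"] = asm.array_length
    report["assembly_length"] = len(asm.sequence)

    # --- enrich (optional) -------------------------------------------------
    if config.run_enrichment:
        from .enrich import kmer_enrichment

        chip, bg = simulate_chip(
            locus, truth, config.enrichment_fold,
            ShortReadModel(coverage=20.0),
            seed=derive_seed(seed, _STAGE_OFFSETS["chip"]),
        )
        track = kmer_enrichment(
            asm.sequence,
            [r for _, r1, r2 in chip for r in (r1, r2)],
            [r for _, r1, r2 in bg for r in (r1, r2)],
        )
        io.write_bedgraph(
            out / "enrichment.bedgraph",
            list(track.windows.itertuples(index=False, name=None)),
        )
        report["enrichment_windows"] = len(track.windows)
    return asm, report


def _non_satellite_regions(
    cons: str, instances: list, monomer: str
) -> list[tuple[int, int]]:
    """Unique regions = everything outside detected HOR array and
    divergent monomeric satellite."""
    if not instances:
        return [(0, len(cons))]
    arr = (instances[0].start, instances[-1].end)
    mono = annotate.detect_monomeric_flanks(cons, monomer, arr)
    blocked = sorted([arr, *mono])
    out = []
    cursor = 0
    for s, e in blocked:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < len(cons):
        out.append((cursor, len(cons)))
    return out
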