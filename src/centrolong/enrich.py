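"""Centromere-protein ChIP enrichment over the assembly.

Array enrichment is computed reference-free at the 50-mer level: for
every assembly 50-mer, the log ratio of its relative frequency in the
ChIP read set versus the background set, averaged over 6 kb windows.
Flank enrichment outside the array uses strictly filtered alignments
(no mismatches or indels, unique placement) with per-base depth
normalized by each data set's total base count.  A per-HOR-unit phase
profile folds read depth onto a single repeat unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmers import count_kmers_long
from .mapping import ShortReadMapper
from .seqs import revcomp


@dataclass
class EnrichmentParams:
    kmer_length: int = 50
    window: int = 6_000
    pseudocount: float = 1.0


@dataclass
class EnrichmentTrack:
    windows: pd.DataFrame  # start, end, mean_log_enrichment
    per_kmer: pd.DataFrame  # pos, kmer, chip_count, bg_count, log_enrichment, fallback
    params: EnrichmentParams = field(default_factory=EnrichmentParams)


def _canon(s: str) -> str:
    rc = revcomp(s)
    return min(s, rc)


def kmer_enrichment(
    assembly: str,
    chip_reads: list[str],
    background_reads: list[str],
    params: EnrichmentParams | None = None,
    fallback_reads: list[str] | None = None,
) -> EnrichmentTrack:
    """Per-assembly-50-mer log enrichment, averaged over tiling windows.

    enrichment = log( (chip_count / chip_total) / (bg_count / bg_total) ).
    A 50-mer absent from the background falls back to the alternate
    background set when given, else to a pseudocount; such positions
    are flagged.  Windows tile from coordinate 0; the last partial
    window keeps its true span.
    """
    p = params or EnrichmentParams()
    if not chip_reads or not background_reads:
        raise ValueError("need non-empty chip and background read sets")
    k = p.kmer_length
    asm = assembly.upper()
    chip = count_kmers_long(chip_reads, k)
    bg = count_kmers_long(background_reads, k)
    fb = count_kmers_long(fallback_reads, k) if fallback_reads else None
    chip_total = max(sum(chip.values()), 1)
    bg_total = max(sum(bg.values()), 1)
    fb_total = max(sum(fb.values()), 1) if fb else 1
    rows = []
    for i in range(len(asm) - k + 1):
        km = _canon(asm[i : i + k])
        c = chip.get(km, 0)
        b = bg.get(km, 0)
        fallback = False
        num = (c if c > 0 else p.pseudocount) / chip_total
        if b > 0:
            den = b / bg_total
        elif fb is not None and fb.get(km, 0) > 0:
            den = fb[km] / fb_total
            fallback = True
        else:
            den = p.pseudocount / bg_total
            fallback = True
        rows.append((i, km, c, b, math.log(num / den), fallback))
    per_kmer = pd.DataFrame(
        rows, columns=["pos", "kmer", "chip_count", "bg_count", "log_enrichment", "fallback"]
    )
    win_rows = []
    for ws in range(0, len(asm), p.window):
        we = min(ws + p.window, len(asm))
        sel = per_kmer[(per_kmer.pos >= ws) & (per_kmer.pos < we)]
        vals = sel.log_enrichment.replace([np.inf, -np.inf], np.nan).dropna()
        win_rows.append((ws, we, float(vals.mean()) if len(vals) else float("nan")))
    windows = pd.DataFrame(win_rows, columns=["start", "end", "mean_log_enrichment"])
    return EnrichmentTrack(windows=windows, per_kmer=per_kmer, params=p)


def flank_enrichment(
    assembly: str,
    array_interval: tuple[int, int],
    chip_reads: list[str],
    input_reads: list[str],
    pseudocount: float = 1.0,
    mapper: ShortReadMapper | None = None,
) -> pd.DataFrame:
    """Per-position chip/input log depth ratio outside the array.

    Only perfect (no mismatch/indel), uniquely placed alignments that
    fall outside the array interval count; depth is normalized by the
    total bases in each read set.
    """
    arr_s, arr_e = array_interval
    if mapper is None:
        mapper = ShortReadMapper(assembly)
    L = len(assembly)

    def depth_of(reads: list[str]) -> tuple[np.ndarray, int]:
        depth = np.zeros(L)
        total_bases = sum(len(r) for r in reads)
        for i, r in enumerate(reads):
            m = mapper.map_read(r, f"r{i}")
            if m is None or m.nm != 0 or m.mapq == 0:
                continue
            if m.ref_start >= arr_s and m.ref_end <= arr_e:
                continue  # inside the array: ignored
            depth[m.ref_start : m.ref_end] += 1
        return depth, max(total_bases, 1)

    chip_depth, chip_total = depth_of(chip_reads)
    in_depth, in_total = depth_of(input_reads)
    chip_norm = (chip_depth + pseudocount / L) / chip_total
    in_norm = (in_depth + pseudocount / L) / in_total
    ratio = np.log(chip_norm / in_norm)
    outside = np.ones(L, dtype=bool)
    outside[arr_s:arr_e] = False
    return pd.DataFrame(
        {"pos": np.arange(L)[outside], "log_ratio": ratio[outside],
         "chip_depth": chip_depth[outside], "input_depth": in_depth[outside]}
    )


def hor_phase_profile(
    hor_consensus: str,
    array_reads: list[str],
    mapper: ShortReadMapper | None = None,
) -> np.ndarray:
    """Per-base read depth along one HOR unit.

    The unit is indexed in tandem (duplicated) to avoid edge effects
    and depths are folded back onto a single unit frame.
    """
    L = len(hor_consensus)
    doubled = hor_consensus.upper() * 2
    if mapper is None:
        mapper = ShortReadMapper(doubled)
    depth = np.zeros(2 * L)
    for i, r in enumerate(array_reads):
        m = mapper.map_read(r, f"r{i}")
        if m is None:
            continue  # multi-mapping is expected here (tandem index)
        depth[m.ref_start : m.ref_end] += 1
    return depth[:L] + depth[L:]
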