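"""File formats: FASTA/FASTQ via Biopython, BED/TSV/bedGraph as plain
tables, YAML configs.  All intervals on disk are 0-based half-open;
lowercase masking in FASTA is preserved on round trip."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .validate import SatVar


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(
    path: str | Path, records: list[tuple[str, str]], quality: int = 30
) -> None:
    recs = []
    for name, seq in records:
        r = SeqRecord(Seq(seq.upper()), id=name, description="")
        r.letter_annotations["phred_quality"] = [quality] * len(seq)
        recs.append(r)
    SeqIO.write(recs, str(path), "fastq")


def write_pairs(
    prefix: str | Path, pairs: list[tuple[str, str, str]], quality: int = 30
) -> tuple[Path, Path]:
    p1 = Path(f"{prefix}_R1.fastq")
    p2 = Path(f"{prefix}_R2.fastq")
    write_fastq(p1, [(rid, r1) for rid, r1, _ in pairs], quality)
    write_fastq(p2, [(rid, r2) for rid, _, r2 in pairs], quality)
    return p1, p2


def read_pairs(r1_path: str | Path, r2_path: str | Path) -> list[tuple[str, str, str]]:
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ParseError("R1/R2 record counts differ")
    return [(id1, s1, s2) for (id1, s1), (_, s2) in zip(r1, r2)]


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV


def write_bed(
    path: str | Path, intervals: list[tuple], chrom: str = "assembly"
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            s, e = iv[0], iv[1]
            rest = "\t".join(str(x) for x in iv[2:])
            fh.write(f"{chrom}\t{s}\t{e}" + (f"\t{rest}" if rest else "") + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    for ln, line in enumerate(open(path), 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: malformed BED line")
        try:
            out.append((int(parts[1]), int(parts[2]), *parts[3:]))
        except ValueError as e:
            raise ParseError(f"{path}:{ln}: {e}") from e
    return out


def write_bedgraph(
    path: str | Path, rows: list[tuple[int, int, float]], chrom: str = "assembly"
) -> None:
    with open(path, "w") as fh:
        for s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def write_satvars(path: str | Path, satvars: list[SatVar]) -> None:
    df = pd.DataFrame([dataclasses.asdict(v) for v in satvars])
    df.to_csv(path, sep="\t", index=False)


def read_satvars(path: str | Path) -> list[SatVar]:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"ref": str, "alt": str, "spanning_kmer": str},
        keep_default_na=False,
    )
    out = []
    for _, row in df.iterrows():
        out.append(
            SatVar(
                name=str(row["name"]),
                consensus_position=int(row["consensus_position"]),
                kind=str(row["kind"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                spanning_kmer=str(row["spanning_kmer"]),
                kmer_depth=int(row["kmer_depth"]),
                supporting_kmer_count=int(row["supporting_kmer_count"]),
                alignment_support_fraction=(
                    float(row["alignment_support_fraction"])
                    if str(row["alignment_support_fraction"]) not in ("", "nan")
                    else float("nan")
                ),
                validated=str(row["validated"]) in ("True", "true", "1"),
                edge=str(row["edge"]) in ("True", "true", "1"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# config


def write_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
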