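#!/usr/bin/env python
"""Generate the synthetic centromeric satellite loci used throughout.

Writes the desk-scale locus (1.2 kb HORs x 20, three structural
variants in two clusters, nine planted single-copy variants, three
haplotype blocks) and a full-scale locus (5.8 kb HORs x 52, seven
structural variants) with their ground-truth tracks under results/.
"""

from pathlib import Path

import pandas as pd

from centrolong import io
from centrolong.simulate import full_scale_spec, make_array, scaled_spec

OUT = Path(__file__).resolve().parent.parent / "results" / "locus"
OUT.mkdir(parents=True, exist_ok=True)


def emit(tag: str, spec) -> dict:
    locus, truth = make_array(spec)
    io.write_fasta(OUT / f"{tag}_locus.fa", [(tag, locus)])
    io.write_fasta(OUT / f"{tag}_hor_reference.fa", [("hor_ref", truth.canonical_unit)])
    io.write_bed(OUT / f"{tag}_hors.bed", truth.hor_intervals, chrom=tag)
    rows = [
        {"name": v.name, "hor": v.hor_index, "locus_pos": v.locus_pos,
         "kind": v.kind, "ref": v.ref, "alt": v.alt, "kmer": v.spanning_kmer}
        for v in truth.planted_variants
    ]
    pd.DataFrame(rows).to_csv(OUT / f"{tag}_variants.tsv", sep="\t", index=False)
    n_struct = sum(1 for *_, c in truth.hor_intervals if c == "structural")
    arr_s, arr_e = truth.array_interval
    return {
        "locus": tag,
        "length_bp": len(locus),
        "array_bp": arr_e - arr_s,
        "hor_units": len(truth.hor_intervals),
        "structural_units": n_struct,
        "planted_variants": len(truth.planted_variants),
    }


def main() -> None:
    summary = pd.DataFrame([
        emit("scaled", scaled_spec(seed=1)),
        emit("full", full_scale_spec(seed=1)),
    ])
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nArtifacts under {OUT}")


if __name__ == "__main__":
    main()
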