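# centrolong

Assembly and validation of tandemly repeated satellite DNA — the
higher-order repeat (HOR) arrays of human centromeres — from clone-based
(BAC) long-read sequencing, with short-read validation of the rare
single-copy variants that make such an assembly checkable.

Centromeric alpha satellite is organised as a chromosome-specific HOR
unit (~171 bp monomers, units of a few kb) repeated head-to-tail tens to
hundreds of times at >99% identity. No read overlapper can order such an
array from read similarity alone; the information that fixes the layout
is the handful of *single-copy* variants (satVARs) scattered across
otherwise identical units. `centrolong` implements the full protocol at
clone granularity:

1. **Read selection** — full-length reads of a linearized circular
   vector+insert clone are recognised by carrying ≥3 kb of cloning-vector
   sequence, and rotated to a common frame starting at the
   vector→insert junction.
2. **Sampled-MSA consensus** — ten random samples of 60 full-length
   reads; per sample a multiple alignment and a column-rule consensus
   (majority base; a gap deletes a column only when the best nucleotide
   there is seen in fewer than ten reads); a meta-consensus over the ten
   drafts.
3. **Polishing** — all full-length reads re-aligned to the consensus:
   bases below half the average coverage are removed, bases with <50%
   read support are lowercase-masked; on unique (non-satellite) flanks a
   stricter short-read polish substitutes a base when ≥80% of mapQ≥20
   reads agree.
4. **satVAR validation** — a candidate variant is accepted when its
   spanning 21-mer (i) matches neither vector nor canonical HOR repeat,
   (ii) occurs exactly once in the consensus, and (iii) has a read
   k-mer depth inside the single-copy range calibrated from vector
   k-mers, supported by ≥2 overlapping read k-mers — or, by alignment,
   when ≥80% of mapQ-filtered covering reads support it at single-copy
   coverage.
5. **Overlap-layout assembly** — clones are ordered p-arm→q-arm by
   shared satVAR signatures at consistent spacings plus arm-anchor
   alignments, and merged at overlap midpoints.
6. **HOR annotation** — unit detection by semi-global tiling of the
   canonical repeat, structural (length) variant classification and
   clustering, pairwise unit identities, haplotype grouping from
   array-frequent variants, divergent monomeric flank detection.
7. **ChIP enrichment** — reference-free 50-mer frequency log-ratios
   (ChIP vs background) averaged over 6 kb windows, strict perfect-unique
   flank mapping, and a per-HOR-unit phase profile.

A first-class synthetic-data generator (`centrolong.simulate`) plants a
fully known locus — HOR array with structural variants, haplotype
blocks, single-copy variants, divergent monomeric + unique flanks;
circular clone constructs; nanopore-like long reads (~85% identity,
both strands, random circular cut); MiSeq-like paired reads; enriched
ChIP read sets — so every stage is tested against ground truth.

## Worked example

Run the whole pipeline on the desk-scale synthetic locus (1.2 kb HORs ×
20 units, three clones, ~2 minutes on one core):

```
$ centrolong run --seed 11 --outdir run1
{
  "locus_length": 40720,
  "true_bac_order": ["bac00", "bac01", "bac02"],
  "bac00_selected": 215,
  "bac00_satvars": 4,
  "bac01_selected": 204,
  "bac01_satvars": 3,
  "bac02_selected": 195,
  "bac02_satvars": 5,
  "assembly_order": ["bac00", "bac01", "bac02"],
  "hor_count": 20,
  "array_length": 24720,
  "assembly_length": 40720
}
```

Reading this: per clone, ~200 of 400 simulated reads were recognised as
full-length and reoriented; after consensus + polishing, the validated
satVARs per clone are the planted variants falling in that clone's
insert; the three clones were ordered correctly and the merged assembly
reproduces the planted 40,720 bp locus (20 HOR units, 24,720 bp array)
at 99.995% identity (`analysis/02_clone_pipeline.py` prints the full
report with `assembly_identity_to_truth`).

Every stage is also exposed on its own (`centrolong simulate | select |
consensus | validate | annotate | assemble | enrich`), and the
`analysis/` scripts run the larger studies: locus generation at full
scale (52 × 5.8 kb units, ~304 kb array), the variant-detection and
false-positive simulations, full-scale HOR annotation, and the ChIP
enrichment profile.

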