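# Methods

`centrolong` reconstructs a tandem satellite (alpha satellite HOR) array
from clone-based long reads and validates it with short reads. This note
records the models, the rules actually applied at each stage, the
numerical choices made where the design was open, and what the synthetic
data do and do not establish.

## The problem and the information model

A centromeric HOR array is a unit of a few kilobases repeated
head-to-tail at >99% identity. Within one clone (a circular
vector+insert construct of the array plus, for terminal clones, flanking
divergent monomeric satellite and unique arm sequence), read-to-read
similarity cannot order the units; the only positional information is
(a) the vector→insert junction, (b) rare single-copy variants
("satVARs") whose 21-mer context occurs exactly once, (c) structural
(length) variant units, and (d) the unique arms. The pipeline is
organised entirely around extracting and cross-checking that
information.

## Synthetic data generator

The generator is first-class, tested code; all downstream recovery tests
score against its truth records.

* **Array.** A random monomer (default 200 bp at desk scale, 171 bp at
  full scale) is diverged per monomer position (20% substitutions) to
  form the canonical unit; the unit is repeated `hor_count` times.
  Structural variants insert a block of `length_delta` random bases
  mid-unit — one shared block per distinct delta, since the real array
  carries a single repeated variant type; random content keeps the unit
  junctions alignment-unambiguous, which monomer-derived content would
  not (the source material does not specify the block's internal
  structure). Haplotype sites are substitutions applied per block
  (labels are bit-strings over the site list; blocks tile the array).
  Single-copy variants (SUB/INS/DEL) are applied at unique
  (unit, offset) pairs; generation retries with a derived seed until
  every variant's spanning 21-mer is unique in the locus in either
  orientation. Flanks: divergent monomeric satellite (monomer copies at
  20% divergence, a small indel load) inside unique random "arm"
  sequence.
* **Desk scale vs full scale.** Tests run at 200 bp × 6 = 1.2 kb units,
  20 copies, 3 clones (constructs ≈ 24 kb) — chosen so the whole
  pipeline, including ten 60-read alignment rounds per clone, runs in
  minutes. `full_scale_spec` (171 bp × 34 ≈ 5.8 kb units, 52 copies,
  7 structural variants in two clusters) reproduces the real geometry
  (~304 kb array) and is used in `analysis/`.
* **Long reads.** Outcome-level model: per-true-base error rate `e`
  derived in closed form from the target alignment identity `I` and the
  mismatch/insertion/deletion mix `(m, i, d)`:
  `I = (1 − e(m+d)) / (1 + e·i)`, so `e = (1−I)/(m + d + I·i)`
  (`I = 0.848` default → `e ≈ 0.159` at mix 0.40/0.30/0.30). Indel
  probabilities are multiplied by a homopolymer bias (default 2 in runs
  of ≥3). Raw-read error composition is not published for this
  chemistry — only consensus-level proportions — so the mix is an
  exposed parameter. A read is full-length with probability
  `full_length_fraction`, starting at a uniform cut point on the circle
  (a single transposase cut); truncations keep a uniform(0.1, 0.9)
  prefix. Strands are balanced.
* **Short reads.** Fixed read length (250 bp), Gaussian fragments
  (400 ± 40 bp; draws below the read length are resampled), i.i.d.
  substitutions (default 0.004/base, a raw MiSeq-like rate), inward
  pairs; pair count = coverage × length / (2 × read length). Clone
  resequencing uses `circular=True`, which removes the coverage ramp of
  linear ends — without it, vector k-mers at the construct end have
  near-zero depth and corrupt the single-copy depth calibration.
* **ChIP.** Fragment start weights are `fold` inside the array and 1
  outside; background is uniform. With total-count normalization the
  absolute track level depends on the array's fraction of the locus;
  the array-minus-flank contrast equals `log(fold)` exactly, and that is
  what tests assert.

Not modelled: signal-level nanopore behaviour, quality-string realism
(constant Q), GC/PCR bias, chimeric reads, cloning bias. Passing tests
therefore demonstrate correctness of the *decision rules* under a
faithful error-magnitude model, not robustness to instrument-specific
artefacts.

## Read selection and reorientation

Vector presence is scored by aligning non-overlapping 500 bp vector
tiles to the read (both strands, edlib infix mode; a tile counts below
40% divergence), so a vector split across the ends of a rotated read is
fully credited; the anchor requires ≥3,000 matched vector bases.
Full-length reads are rotations of the circle: the read is rotated to
start right after the match of the vector's terminal 3 kb (the
vector→insert transition). If the cut fell inside that window the read
is first rotated to the vector head and retried. Insert-length bounds
default to the modal (length-weighted) read length ±10% from the yield
curve. On error-free reads selection recovers exactly the planted
full-length set; strand balance is binomial.

## Multiple alignment and consensus

The multiple aligner is a **star MSA**: each read is globally aligned
(edlib, unit costs) to a scaffold read — the median-length read, since
the longest read at ~16% error is insertion-enriched and would bias the
column frame. Scaffold positions define main columns; read insertions
relative to the scaffold become left-aligned extra columns sized by the
longest insertion at that junction. Every input base occupies exactly
one column and column order respects base order. On ≤20 bp triplets the
result matches an exhaustive three-sequence DP at sum-of-pairs cost
(tested); at scale it is approximate but feeds a consensus that the
polishing stage corrects.

Column rules (`call_consensus`): most frequent symbol wins; when the gap
is most frequent the column is deleted **only if** the best nucleotide
there is seen in fewer than `gap_second_base_min = 10` sequences,
otherwise that nucleotide is called; base ties break A<C<G<T. This gap
rule is what removes scaffold-insertion artefacts (columns where most
reads show a gap) without deleting genuine low-support bases.

`iterate_consensus` draws 10 independent samples of 60 reads (without
replacement within a sample), builds one draft each, then calls a
meta-consensus over a star MSA of the ten drafts **with the same
absolute 10-read threshold**, which at depth 10 reduces to a strict
majority. We measured the alternative (rescaling the threshold to the
meta depth, 10/60 → 2/10): it retains correlated draft insertion errors
and degrades the meta-consensus below the best single draft (94.9% vs
96.8% on the scaled construct), while the absolute rule reaches 99.87%
before polishing. Sample independence matters: with only ~60 available
full-length reads the ten samples are nearly identical and the meta
stage cannot average draft errors — the default simulation therefore
provides ~200 full-length reads per clone, matching the >3,500
full-length reads over ten clones of the real data set.

**Long-read polish**: every full-length read is re-aligned to the
consensus; per position, coverage = reads whose alignment spans it.
Average coverage is computed before filtering; positions below half of
it are removed; the majority read base replaces the consensus base
(ties prefer the existing base, then A<C<G<T); a majority deletion
removes the base; retained bases with <50% support are
lowercase-masked. **Short-read polish** (unique regions only): mapQ<20
alignments are discarded; a base is substituted when ≥80% of covering
reads agree and coverage is at least half the consensus-wide average.
The pileup polisher substitutes only — indel correction is out of scope
— so draft indels bound attainable identity (see the polishing study).

## Short-read mapper

A minimal seed(31-mer)-and-extend mapper over one reference: seed
diagonals on both strands, edlib refinement, best placement by edit
distance. Mapping quality is binary — 60 for a unique best placement, 0
when the best score occurs at more than one location (deduplicated
within 10 bp) — which is precisely the semantics the mapQ ≥ 20 filters
need inside near-identical repeats (q=20 ⇔ 99% placement confidence).
Reads above 25% divergence are unmapped.

## satVAR validation

Candidates are single-base differences between length-canonical HOR
instances of the consensus and the canonical repeat (global alignment
per unit). Structural-length units and partial units are *excluded* as
candidate sources: a structural variant acts as a whole-unit marker, not
as a bag of internal differences. Candidates within 21 bp of a
consensus end are reported as unvalidatable (`edge`).

* **k-mer route**: the spanning 21-mer must label as neither `vector`
  nor `ceny` (exact canonical match against vector / HOR reference,
  junction k-mers of the tandem unit included), occur exactly once in
  the consensus (both orientations), and have read-table depth inside
  the single-copy range with ≥2 of the 21 variant-overlapping read
  k-mers inside that range.
* **alignment route**: same uniqueness requirement; then ≥80% of
  mapQ-filtered covering reads must carry the variant and site coverage
  must lie inside the single-copy range.
* **Single-copy depth range**: quantiles of the vector-labelled k-mer
  depth distribution. Default (0, 1) — the full observed extent. A
  tight central quantile pair (e.g. 0.5%/99.5%) rejects ~1% of genuinely
  single-copy sites by construction, because a variant's depth is one
  more draw from the same distribution; the published worked range
  (1,100–1,600× around a ~1,350× median) likewise spans far more than
  the distribution's central 99%. Quantiles remain configurable.
* k-mers are counted canonically (lexicographic min of the two
  orientations) with a vectorized 2-bit rolling encoder (k ≤ 31) or a
  dictionary (k = 50), cross-checked against a brute-force counter.

Copy number = median `ceny` k-mer depth / median `vector` k-mer depth.
Its sampling noise is driven by fragment-start clustering, roughly
`1/sqrt(coverage × region/500 bp)` per median; the synthetic panel
correlation test sizes regions accordingly.

## Simulation studies

* **Mapping study** (10 identical ~5.8 kb units, one random single-base
  change, paired reads mapped back to the variant-bearing reference):
  a trial is a true call when ≥80% of mapQ-filtered reads covering the
  site support the variant and site coverage reaches half the nominal
  coverage — the single-copy analogue of the half-average rule; the
  published study's own depth criterion (vector distribution) has no
  vector in this design and is not further specified. Only read pairs
  whose true origin lies within a read length of a position homologous
  to the variant are mapped: any other read either maps elsewhere or
  multi-maps and is removed by the mapQ filter, so support and coverage
  are unchanged and 100 trials run in ~2 minutes. At 100× and default
  error the true-call count is ~97/100; failures are variants landing in
  the low-coverage ramp near the array ends. Reads simulated from the
  variant-free array never reach validation coverage: every such read is
  either exactly repeated across units (multi-maps) or supports the
  variant only through a coincidental error at negligible depth.
* **False-positive study**: 1,000 random single-base injections into the
  array; the injected variant's spanning 21-mers are queried against the
  k-mer table of reads from the *unmodified* construct under the
  depth-range criteria. Error-derived k-mers appear at depth ~1–3
  against a single-copy range of ~50–90 at 100×, so 0/1,000 validate;
  widening the range to [1, ∞) makes false calls appear (sanity
  inversion).
* **Polishing study** (73 kb unique control, 30×): the draft carries
  1.0% substitutions + 0.1% single-base indels, emulating a long-read
  consensus; the mapQ ≥ 20 / 80%-support substitution polish restores
  ≥99.8% identity (the indel load bounds the ceiling at ~99.9%).
  Identity is global-alignment matches over columns.

## Assembly

Pairs of clones sharing satVAR signatures — same kind and alleles, and
identical spanning 21-mer when both sides carry one (the 21-mer *is* the
variant's identity, so spurious matches cannot form) — receive an offset
from the largest spacing-consistent cluster of position differences
(tolerance 200 bp; the median difference is the offset, and pairs whose
matches disagree in spacing are rejected). Clones aligning to the p- or
q-arm anchor at ≥95% identity over ≥5 kb (tile-counted) fix the ends.
Placements are chained by BFS from the p-terminal clone; any
re-placement disagreeing by more than 500 bp is a hard error
(contradictory evidence), as is a disconnected graph. A single shared
satVAR suffices for an edge on the anchored chain. Merging switches
between clones at the overlap midpoint; assembly metrics (HOR count,
array length, alpha satellite span) come from re-annotation of the
merged sequence. Consensus indel noise shifts satVAR coordinates by
much less than the 200 bp tolerance at the identities polishing reaches.

## HOR annotation

Units are found by greedy non-overlapping semi-global tiling of the
canonical repeat (edlib infix alignment, identity = matches/columns,
default threshold 0.8) — on near-identical tandem arrays this is
equivalent to a profile-HMM scan and trivially verifiable. Interior
gaps between adjacent instances (≤ half a unit) are absorbed into the
neighbour with the weaker alignment — a structural unit aligns
partially and leaves its insert as exactly such a gap; when both
neighbours are equally weak (adjacent structural units) the gap is
split to equalize their lengths. Structural classification is by length
departure beyond a tolerance (default 100 bp), with clusters = runs of
adjacent structural units. Pairwise unit identity uses Biopython's
affine-gap global aligner (match 1 / mismatch −1 / open −2 / extend
−0.5), identity = matches/columns; note that with structural variants
included the mean is pulled down by gap columns (a ~240 bp insert in a
1.2 kb unit costs ~17 points against canonical partners). The variant
matrix records substitutions and single-base deletions at reference
offsets; frequent columns are those whose minor alleles total ≥4 units;
a haplotype is the allele tuple at frequent columns, labelled by first
occurrence; blocks are runs of identical labels with single-unit strays
absorbed when the flanking label keeps >50% frequency. Monomeric flanks
are tiled with the monomer at ≥0.6 identity outside the array.

## ChIP enrichment

For every assembly 50-mer: `log((chip_count/chip_total) /
(bg_count/bg_total))` (natural log; the base affects only scale). A
50-mer unseen in the background falls back to the alternate background
set, else to a pseudocount of 1, and is flagged; flagged rows are where
exact scale invariances cannot hold (no additive constant is scale-free
at zero counts). Window means tile from coordinate 0 in 6 kb windows,
the last window keeping its true span. Flank profiling admits only
perfect (edit distance 0), uniquely placed alignments outside the array,
with per-base depth normalized by each set's total bases. The per-unit
phase profile maps array reads to the unit doubled in tandem (avoiding
edge effects) and folds depths back onto one unit frame, conserving
aligned bases.

## Determinism

Every stochastic operation takes an explicit integer seed
(`numpy.random.Generator(PCG64)`); no global state. Pipeline stages
derive fixed-offset child seeds from one master seed, so a `RunConfig`
reproduces byte-identical artifacts. Applied thresholds (60 reads, 10
iterations, 10-read gap rule, 3 kb vector span, 80% support, mapQ 20,
k = 21, k = 50, 6 kb windows) are logged at run time.

## Known limitations

* The star MSA is a consensus-grade aligner, not a general MSA; its
  insertion columns are left-aligned and may smear homopolymer indels
  (polishing absorbs this downstream).
* The pileup polishers substitute; they do not fix indels.
* Variants inside structural-variant units are not validated as satVARs
  (the unit itself is the marker), and variants recurring within a
  clone are out of scope by design.
* The internal mapper assumes one moderate-size reference; it is not a
  general-purpose aligner.
* Inverted or transposon-interrupted arrays are out of scope; the array
  is assumed head-to-tail as in the modelled locus.
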