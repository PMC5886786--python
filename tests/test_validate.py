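"""k-mer tables, pair merging, depth calibration, satVAR validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_kmer_counts

from centrolong.kmers import (
    KmerTable,
    build_labels,
    count_kmers,
    count_kmers_long,
    encode_kmer,
)
from centrolong.rngs import make_rng
from centrolong.seqs import random_seq, revcomp
from centrolong.simulate import (
    ArraySpec,
    ShortReadModel,
    default_vector,
    make_array,
    simulate_short_reads,
)
from centrolong.validate import (
    DepthRange,
    ValidationParams,
    call_satvars_kmer,
    estimate_copy_number,
    find_candidate_variants,
    merge_pairs,
    validate_satvars_alignment,
    vector_depth_range,
)

dna = st.text(alphabet="ACGT", min_size=25, max_size=200)


class TestKmerCounting:
    @settings(derandomize=True, max_examples=25)
    @given(dna)
    def test_matches_brute_force_dictionary_count(self, seq):
        table = count_kmers([seq], k=21)
        expected = brute_force_kmer_counts([seq], 21)
        assert table.total == sum(expected.values())
        for km, n in expected.items():
            assert table.get(km) == n

    @settings(derandomize=True, max_examples=25)
    @given(dna)
    def test_strand_symmetric(self, seq):
        t1 = count_kmers([seq], k=21)
        t2 = count_kmers([revcomp(seq)], k=21)
        assert np.array_equal(t1.kmers, t2.kmers)
        assert np.array_equal(t1.counts, t2.counts)

    def test_long_k_counter_matches_brute_force(self):
        seq = random_seq(2_000, make_rng(41))
        counted = count_kmers_long([seq], k=50)
        assert counted == brute_force_kmer_counts([seq], 50)

    def test_ambiguous_bases_skipped(self):
        table = count_kmers(["ACGTN" + "ACGT" * 10], k=21)
        brute = brute_force_kmer_counts(["ACGTN" + "ACGT" * 10], 21)
        assert table.total == sum(brute.values())


class TestLabels:
    def test_vector_only_sequence_all_vector(self, vector):
        labels = build_labels(vector, "ACGT" * 100, k=21)
        table = count_kmers([vector[100:400]], k=21)
        assert (labels.label_all(table.kmers) == 0).all()

    def test_hor_reference_all_ceny(self, scaled_locus, vector):
        _, truth = scaled_locus
        labels = build_labels(vector, truth.canonical_unit, k=21)
        table = count_kmers([truth.canonical_unit], k=21)
        assert (labels.label_all(table.kmers) == 1).all()

    def test_planted_snv_creates_k_novel_other_kmers(self, vector):
        unit = random_seq(500, make_rng(42))
        pos = 250
        alt = "A" if unit[pos] != "A" else "G"
        mutated = unit[:pos] + alt + unit[pos + 1 :]
        labels = build_labels(vector, unit, k=21)
        novel = [
            mutated[s : s + 21]
            for s in range(pos - 20, pos + 1)
            if labels.label(mutated[s : s + 21]) == "other"
        ]
        assert len(novel) == 21


class TestMergePairs:
    def test_overlap_arithmetic(self):
        frag = random_seq(400, make_rng(43))
        merged = merge_pairs([("p", frag[:250], revcomp(frag)[:250])])
        assert len(merged) == 1
        assert merged[0][1] == frag

    def test_non_overlapping_pair_passes_through(self):
        frag = random_seq(600, make_rng(44))
        out = merge_pairs([("p", frag[:250], revcomp(frag)[:250])])
        assert len(out) == 2
        assert out[0][1] == frag[:250]
        assert out[1][1] == frag[350:]

    def test_error_free_simulation_merges_all_overlapping_pairs(self):
        seq = random_seq(8_000, make_rng(45))
        model = ShortReadModel(substitution_rate=0.0, coverage=20, fragment_sd=30)
        pairs, origins = simulate_short_reads(seq, model, seed=46)
        merged = dict(merge_pairs(pairs))
        for rid, r1, r2 in pairs:
            o = origins[rid]
            if o.length <= 490:  # >= 10 bp overlap at 2 x 250
                assert merged[rid] == seq[o.start : o.start + o.length]


class TestDepthCalibration:
    def test_uniform_depth_gives_point_range(self, vector):
        labels = build_labels(vector, "ACGTACGTAC" * 100, k=21)
        table = count_kmers([vector], k=21)  # every vector k-mer once
        rng = vector_depth_range(table, labels, pad=0.0)
        assert (rng.low, rng.high) == (1, 1)
        # the default padding brackets the uniform depth
        assert vector_depth_range(table, labels).contains(1)

    def test_too_few_vector_kmers_rejected(self, vector):
        labels = build_labels(vector, "ACGT" * 100, k=21)
        table = count_kmers([vector[:80]], k=21)
        with pytest.raises(ValueError, match="vector k-mers"):
            vector_depth_range(table, labels)

    def test_planted_single_copy_depth_falls_inside_range(self, vector):
        spec = ArraySpec(hor_count=6, seed=47,
                         single_copy_variants=[(2, 700, "SUB", "A")],
                         flank_monomeric=0, flank_arm=0)
        locus, truth = make_array(spec)
        construct = vector + locus
        misses = 0
        for seed in range(5):
            pairs, _ = simulate_short_reads(
                construct, ShortReadModel(coverage=100), seed=seed, circular=True
            )
            table = count_kmers([r for _, r1, r2 in pairs for r in (r1, r2)], k=21)
            labels = build_labels(vector, truth.canonical_unit, k=21)
            rng = vector_depth_range(table, labels)
            depth = table.get(truth.planted_variants[0].spanning_kmer)
            if not rng.contains(depth):
                misses += 1
        assert misses == 0


class TestCopyNumber:
    def _table_labels(self, vector, unit, n_copies, coverage, seed):
        construct = vector + unit * n_copies
        pairs, _ = simulate_short_reads(
            construct, ShortReadModel(coverage=coverage), seed=seed, circular=True
        )
        table = count_kmers([r for _, r1, r2 in pairs for r in (r1, r2)], k=21)
        return table, build_labels(vector, unit, k=21)

    def test_ten_copies_estimated_within_5_percent(self, vector):
        unit = random_seq(1_500, make_rng(48))
        table, labels = self._table_labels(vector, unit, 10, 100, seed=49)
        assert estimate_copy_number(table, labels) == pytest.approx(10, rel=0.05)

    def test_single_copy_estimates_one(self, vector):
        unit = random_seq(4_000, make_rng(50))
        table, labels = self._table_labels(vector, unit, 1, 200, seed=51)
        assert estimate_copy_number(table, labels) == pytest.approx(1, rel=0.05)

    def test_scale_invariance_under_doubled_coverage(self, vector):
        # exact invariance: duplicating every read doubles all k-mer
        # counts and must leave the depth-ratio estimate unchanged
        unit = random_seq(1_500, make_rng(52))
        construct = vector + unit * 5
        pairs, _ = simulate_short_reads(
            construct, ShortReadModel(coverage=60), seed=53, circular=True
        )
        reads = [r for _, r1, r2 in pairs for r in (r1, r2)]
        labels = build_labels(vector, unit, k=21)
        e1 = estimate_copy_number(count_kmers(reads, k=21), labels)
        e2 = estimate_copy_number(count_kmers(reads + reads, k=21), labels)
        assert abs(e1 - e2) / e1 < 0.02
        # independent redraw at doubled coverage agrees within sampling noise
        t2, _ = self._table_labels(vector, unit, 5, 120, seed=54)
        e3 = estimate_copy_number(t2, labels)
        assert abs(e1 - e3) / e1 < 0.15

    def test_correlation_with_truth_across_synthetic_panel(self, vector):
        """Estimated vs true copy number across 10 clones, r >= 0.96."""
        unit = random_seq(1_200, make_rng(54))
        true_n, est_n = [], []
        for i, n in enumerate(range(1, 11)):
            table, labels = self._table_labels(vector, unit, n, 60, seed=60 + i)
            true_n.append(n)
            est_n.append(estimate_copy_number(table, labels))
        r = np.corrcoef(true_n, est_n)[0, 1]
        assert r >= 0.96


class TestKmerValidation:
    def test_below_range_depth_rejected(self):
        unit = random_seq(1_000, make_rng(55))
        cons = unit * 3
        pos = 1_500
        alt = "A" if cons[pos] != "A" else "G"
        cons = cons[:pos] + alt + cons[pos + 1 :]
        reads = [cons[pos - 40 : pos + 40]] * 3  # depth 3 when range needs 1100+
        table = count_kmers(reads, k=21)
        labels = build_labels(default_vector(), unit, k=21)
        cands = find_candidate_variants(cons, unit)
        out = call_satvars_kmer(
            cons, table, labels, DepthRange(1_100, 1_600), candidates=cands
        )
        target = [v for v in out if v.consensus_position == pos]
        assert target and not target[0].validated
        assert target[0].kmer_depth == 3

    def test_single_supporting_kmer_rejected(self):
        unit = random_seq(1_000, make_rng(56))
        cons = unit * 3
        pos = 1_500
        alt = "A" if cons[pos] != "A" else "G"
        cons = cons[:pos] + alt + cons[pos + 1 :]
        # only the central spanning 21-mer present in reads, 5 times
        reads = [cons[pos - 10 : pos + 11]] * 5
        table = count_kmers(reads, k=21)
        labels = build_labels(default_vector(), unit, k=21)
        cands = find_candidate_variants(cons, unit)
        out = call_satvars_kmer(
            cons, table, labels, DepthRange(2, 10), candidates=cands,
            params=ValidationParams(min_overlapping_kmers=2),
        )
        target = [v for v in out if v.consensus_position == pos][0]
        assert target.supporting_kmer_count == 1
        assert not target.validated


class TestAlignmentValidation:
    def _setup(self, n_alt, n_ref):
        rng = make_rng(57)
        cons = random_seq(3_000, rng)
        pos = 1_500
        alt = "A" if cons[pos] != "A" else "G"
        var_cons = cons[:pos] + alt + cons[pos + 1 :]
        alt_reads = [var_cons[pos - 150 : pos + 150]] * n_alt
        ref_reads = [cons[pos - 150 : pos + 150]] * n_ref
        from centrolong.validate import SatVar

        v = SatVar(name="x", consensus_position=pos, kind="SUB",
                   ref=cons[pos], alt=alt)
        return var_cons, alt_reads + ref_reads, v

    def test_85_percent_support_validated(self):
        cons, reads, v = self._setup(85, 15)
        out = validate_satvars_alignment(
            cons, reads, DepthRange(50, 150), candidates=[v]
        )
        assert out[0].validated
        assert out[0].alignment_support_fraction == pytest.approx(0.85)

    def test_79_percent_support_rejected(self):
        cons, reads, v = self._setup(79, 21)
        out = validate_satvars_alignment(
            cons, reads, DepthRange(50, 150), candidates=[v]
        )
        assert not out[0].validated

    def test_multimapping_reads_excluded_from_support(self):
        unit = random_seq(1_200, make_rng(58))
        pos = 600
        alt = "A" if unit[pos] != "A" else "G"
        var_unit = unit[:pos] + alt + unit[pos + 1 :]
        cons = var_unit + unit * 3  # variant unique to copy 1
        # reads lack the variant and sit inside identical repeat copies:
        # they multimap (mapq 0), are dropped, and site coverage stays 0
        reads = [unit[450:750]] * 40
        from centrolong.validate import SatVar

        v = SatVar(name="x", consensus_position=pos, kind="SUB",
                   ref=unit[pos], alt=alt)
        out = validate_satvars_alignment(
            cons, reads, DepthRange(10, 100), candidates=[v]
        )
        assert not out[0].validated
        assert out[0].alignment_support_fraction == 0.0
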