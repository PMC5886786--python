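"""Synthetic-data generator: planted truth, read models, determinism."""

import numpy as np
import pytest

from centrolong.align import edit_distance, identity
from centrolong.rngs import make_rng
from centrolong.seqs import revcomp
from centrolong.simulate import (
    ArraySpec,
    BACSpec,
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


class TestMakeArray:
    def test_full_scale_arithmetic_matches_printed_array_size(self):
        # 45 canonical 5,785 bp units + 7 structural units carrying a
        # 225 bp insert (~6.0 kb) give a ~302 kb array, consistent with
        # the published 301 kb figure.
        spec = ArraySpec(
            monomer_length=5,
            monomers_per_hor=1157,  # 5,785 bp unit
            hor_count=52,
            structural_variants=[(i, 225) for i in (10, 11, 12, 13, 40, 41, 42)],
            flank_monomeric=0,
            flank_arm=0,
            seed=3,
        )
        locus, truth = make_array(spec)
        expected = 45 * 5785 + 7 * 6010
        assert len(locus) == expected
        assert abs(len(locus) - 301_000) / 301_000 < 0.01
        assert len(truth.hor_intervals) == 52
        assert sum(1 for *_, c in truth.hor_intervals if c == "structural") == 7

    def test_single_unit_no_variants(self):
        spec = ArraySpec(hor_count=1, flank_monomeric=200, flank_arm=300, seed=2)
        locus, truth = make_array(spec)
        assert len(truth.hor_intervals) == 1
        s, e, cls = truth.hor_intervals[0]
        assert cls == "canonical"
        assert e - s == spec.unit_length
        assert len(locus) == 2 * (200 + 300) + spec.unit_length

    def test_sixteen_planted_variants_all_unique(self):
        variants = [(i, 137 + 61 * i, "SUB", "ACGT"[i % 4]) for i in range(16)]
        spec = ArraySpec(hor_count=16, single_copy_variants=variants, seed=7)
        locus, truth = make_array(spec)
        assert len(truth.planted_variants) == 16
        kmers = [v.spanning_kmer for v in truth.planted_variants]
        assert len(set(kmers)) == 16
        for km in kmers:
            n = locus.count(km) + (locus.count(revcomp(km)) if revcomp(km) != km else 0)
            assert n == 1

    def test_variant_base_matches_truth_record(self):
        _, truth = make_array(scaled_spec(seed=4))
        for v in truth.planted_variants:
            if v.kind == "SUB":
                assert truth.locus_sequence[v.locus_pos] == v.alt
                assert v.alt != v.ref

    def test_rejects_offset_outside_unit(self):
        with pytest.raises(ValueError, match="outside HOR unit"):
            ArraySpec(hor_count=2, single_copy_variants=[(0, 99_999, "SUB", "A")])

    def test_rejects_bad_haplotype_layout(self):
        with pytest.raises(ValueError, match="tile"):
            ArraySpec(
                hor_count=4,
                haplotype_sites=[(10, "A")],
                haplotype_block_layout=[(0, 2, "0"), (3, 4, "1")],
            )

    def test_deterministic_given_seed(self):
        l1, t1 = make_array(scaled_spec(seed=9))
        l2, t2 = make_array(scaled_spec(seed=9))
        assert l1 == l2
        assert [v.spanning_kmer for v in t1.planted_variants] == [
            v.spanning_kmer for v in t2.planted_variants
        ]


class TestMakeBacs:
    def test_nine_bac_tiling_has_eight_informative_overlaps(self, scaled_locus, vector):
        locus, truth = scaled_locus
        tiling = scaled_tiling(truth, 9, vector)
        bacs = make_bacs(locus, tiling, truth, seed=1)
        assert len(bacs) == 9
        assert truth.bac_order == [f"bac{i:02d}" for i in range(9)]
        n_shared = 0
        for a, b in zip(bacs, bacs[1:]):
            ov_s = max(a.insert_interval[0], b.insert_interval[0])
            ov_e = min(a.insert_interval[1], b.insert_interval[1])
            assert ov_e > ov_s
            if any(ov_s <= v.locus_pos < ov_e for v in truth.planted_variants):
                n_shared += 1
        assert n_shared == 8

    def test_single_bac_trivial_order(self, scaled_locus, vector):
        locus, truth = scaled_locus
        bacs = make_bacs(locus, scaled_tiling(truth, 1, vector), truth, seed=1)
        assert truth.bac_order == ["bac00"]
        assert len(bacs[0].sequence) == len(locus) + len(vector)

    def test_shuffled_tiling_recorded_sorted_by_start(self, scaled_locus, vector):
        locus, truth = scaled_locus
        tiling = scaled_tiling(truth, 3, vector)
        shuffled = [tiling[2], tiling[0], tiling[1]]
        make_bacs(locus, shuffled, truth, seed=1)
        assert truth.bac_order == ["bac00", "bac01", "bac02"]

    def test_tiling_gap_is_an_error_naming_the_pair(self, scaled_locus, vector):
        locus, truth = scaled_locus
        bad = [
            BACSpec("bacA", vector, (0, 10_000)),
            BACSpec("bacB", vector, (20_000, 30_000)),
        ]
        with pytest.raises(ValueError, match="bacA and bacB"):
            make_bacs(locus, bad, truth, seed=1)


class TestLongReads:
    def test_error_free_full_length_reads_are_rotations(self, bac_panel):
        bac = bac_panel[0]
        model = LongReadModel(median_identity=0.999999, full_length_fraction=1.0)
        reads, origins = simulate_long_reads(bac, model, 5, seed=3)
        doubled = bac.sequence + bac.sequence
        for rid, seq in reads:
            fwd = seq if origins[rid].strand == "+" else revcomp(seq)
            assert edit_distance(fwd, doubled[origins[rid].start : origins[rid].start + len(bac.sequence)]) <= len(seq) // 1000 + 1

    def test_realized_identity_near_target(self, bac_panel):
        bac = bac_panel[0]
        model = LongReadModel(median_identity=0.848, full_length_fraction=1.0)
        reads, origins = simulate_long_reads(bac, model, 30, seed=4)
        doubled = bac.sequence + bac.sequence
        idents = []
        for rid, seq in reads[:30]:
            o = origins[rid]
            true = doubled[o.start : o.start + o.length]
            fwd = seq if o.strand == "+" else revcomp(seq)
            idents.append(identity(fwd, true))
        med = float(np.median(idents))
        assert 0.83 <= med <= 0.87

    def test_full_length_fraction_binomial(self):
        model = LongReadModel(full_length_fraction=0.3)
        reads, origins = simulate_long_reads("ACGT" * 2_000, model, 1_000, seed=5)
        n_full = sum(o.full_length for o in origins.values())
        # binomial 99.9% interval around 300
        assert abs(n_full - 300) < 3.3 * np.sqrt(1_000 * 0.3 * 0.7)

    def test_every_read_has_origin_and_determinism(self, bac_panel):
        bac = bac_panel[0]
        r1, o1 = simulate_long_reads(bac, LongReadModel(), 20, seed=6)
        r2, o2 = simulate_long_reads(bac, LongReadModel(), 20, seed=6)
        assert r1 == r2
        assert set(o1) == {rid for rid, _ in r1}


class TestShortReads:
    def test_error_free_pairs_match_reference(self):
        rng = make_rng(1)
        from centrolong.seqs import random_seq

        seq = random_seq(5_000, rng)
        model = ShortReadModel(substitution_rate=0.0, coverage=10)
        pairs, origins = simulate_short_reads(seq, model, seed=2)
        for rid, r1, r2 in pairs[:50]:
            o = origins[rid]
            frag = seq[o.start : o.start + o.length]
            assert r1 == frag[:250]
            assert r2 == revcomp(frag)[:250]

    def test_pair_count_formula(self):
        seq = "ACGT" * 14_250  # 57 kb
        pairs, _ = simulate_short_reads(
            seq, ShortReadModel(coverage=100, substitution_rate=0), seed=3
        )
        assert len(pairs) == round(100 * 57_000 / (2 * 250))

    def test_substitution_rate_realized(self):
        from centrolong.seqs import random_seq

        seq = random_seq(10_000, make_rng(4))
        model = ShortReadModel(substitution_rate=0.004, coverage=200)
        pairs, origins = simulate_short_reads(seq, model, seed=5)
        mism = total = 0
        for rid, r1, r2 in pairs:
            o = origins[rid]
            frag = seq[o.start : o.start + o.length]
            mism += sum(a != b for a, b in zip(r1, frag[:250]))
            mism += sum(a != b for a, b in zip(r2, revcomp(frag)[:250]))
            total += 500
        rate = mism / total
        sigma = np.sqrt(0.004 * 0.996 / total)
        assert total >= 1e6
        assert abs(rate - 0.004) < 3 * sigma


class TestChip:
    @pytest.mark.parametrize("fold,expected", [(1.0, 1.0), (5.0, 5.0)])
    def test_array_to_flank_density_ratio(self, scaled_locus, fold, expected):
        locus, truth = scaled_locus
        model = ShortReadModel(coverage=30, substitution_rate=0.0)
        chip, bg = simulate_chip(locus, truth, fold, model, seed=6)
        arr_s, arr_e = truth.array_interval
        arr_len = arr_e - arr_s
        flank_len = len(locus) - arr_len
        # classify error-free fragments by locating R1 in the locus
        in_n = out_n = 0
        for _, r1, _ in chip:
            pos = locus.find(r1)
            if pos < 0:
                continue
            mid = pos + 200
            if arr_s <= mid < arr_e:
                in_n += 1
            else:
                out_n += 1
        ratio = (in_n / arr_len) / (out_n / flank_len)
        assert ratio == pytest.approx(expected, rel=0.25)
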