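"""MSA construction, consensus column rules, polishing."""

import numpy as np
import pytest

from oracles import optimal_msa3_cost, sp_cost

from centrolong.align import identity
from centrolong.consensus import (
    ColumnProfile,
    ConsensusParams,
    SamplePlan,
    build_msa,
    call_consensus,
    iterate_consensus,
    iterate_consensus_with_drafts,
    polish,
    shortread_polish,
)
from centrolong.rngs import make_rng
from centrolong.seqs import random_seq
from centrolong.simulate import LongReadModel, apply_read_errors


def profile_from_counts(rows):
    """Build a ColumnProfile from per-column {symbol: count} dicts."""
    idx = {b: i for i, b in enumerate("ACGT-")}
    counts = np.zeros((len(rows), 5), dtype=np.int64)
    for c, row in enumerate(rows):
        for sym, n in row.items():
            counts[c, idx[sym]] = n
    return ColumnProfile(counts=counts, depth=int(counts[0].sum()))


class TestBuildMsa:
    def test_identical_sequences_gapless_diagonal(self):
        seq = random_seq(300, make_rng(1))
        msa = build_msa([seq, seq], keep_rows=True)
        assert msa.rows == [seq, seq]
        assert msa.profile.counts[:, 4].sum() == 0

    @pytest.mark.parametrize(
        "a,b,c",
        [
            # single deletion
            ("ACGTTGCAACGTTGCAACG", "ACGTTGCACGTTGCAACG", "ACGTTGCAACGTTGCAACG"),
            # single insertion
            ("GATTACAGATTACAGATTAC", "GATTACAGATTACAGATTAC", "GATTACAGCATTACAGATTAC"),
            # single mismatch
            ("TTGACCATGGTTGACCATGG", "TTGACCATGGTTGACCATGG", "TTGACCTTGGTTGACCATGG"),
            # mismatch + deletion in different sequences
            ("CCATTGAGCCATTGAGCCAT", "CCATTGAGCCATTGAGCCAT"[:9] + "CATTGAGCCAT", "CCATTGAGCCGTTGAGCCAT"),
        ],
    )
    def test_star_msa_matches_exhaustive_three_sequence_dp(self, a, b, c):
        msa = build_msa([a, b, c], keep_rows=True)
        # every base in exactly one column, order preserved
        for seq, row in zip((a, b, c), msa.rows):
            assert row.replace("-", "") == seq
        assert sp_cost(msa.rows) == optimal_msa3_cost(a, b, c)

    def test_sixty_error_free_copies_consensus_equals_truth(self):
        truth = random_seq(5_000, make_rng(2))
        msa = build_msa([truth] * 60)
        assert call_consensus(msa.profile) == truth

    def test_rejects_wildly_different_lengths(self):
        with pytest.raises(ValueError, match="2x"):
            build_msa(["A" * 100, "A" * 300])

    def test_rejects_single_sequence(self):
        with pytest.raises(ValueError):
            build_msa(["ACGT"])


class TestCallConsensus:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ({"A": 40, "G": 15, "-": 5}, "A"),  # plain majority
            ({"-": 35, "A": 25}, "A"),  # gap majority suppressed (25 >= 10)
            ({"-": 55, "A": 5}, ""),  # gap wins, column deleted (5 < 10)
            ({"-": 50, "A": 9}, ""),  # boundary: 9 < 10 -> deleted
            ({"-": 50, "A": 10}, "A"),  # boundary: 10 -> base emitted
            ({"A": 10, "C": 10}, "A"),  # tie broken in fixed A<C<G<T order
        ],
    )
    def test_column_rules(self, column, expected):
        profile = profile_from_counts([column])
        assert call_consensus(profile) == expected

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            call_consensus(ColumnProfile(np.zeros((0, 5), dtype=np.int64), 0))


class TestIterateConsensus:
    def test_error_free_reads_meta_equals_truth(self):
        truth = random_seq(3_000, make_rng(3))
        meta = iterate_consensus([truth] * 30, SamplePlan(20, 5, seed=1))
        assert meta == truth

    def test_single_iteration_degenerates_to_one_sample(self):
        truth = random_seq(2_000, make_rng(4))
        meta = iterate_consensus([truth] * 10, SamplePlan(10, 1, seed=2))
        assert meta == truth

    def test_deterministic_given_seed(self):
        rng = make_rng(5)
        truth = random_seq(2_000, rng)
        model = LongReadModel(median_identity=0.9)
        reads = [apply_read_errors(truth, model, rng) for _ in range(30)]
        m1 = iterate_consensus(reads, SamplePlan(20, 3, seed=9))
        m2 = iterate_consensus(reads, SamplePlan(20, 3, seed=9))
        assert m1 == m2

    def test_sampling_plus_polish_improves_over_drafts(self):
        """Median polished identity >= median draft identity over seeds."""
        truth = random_seq(4_000, make_rng(6))
        model = LongReadModel(median_identity=0.85)
        draft_idents, polished_idents = [], []
        for seed in range(5):
            rng = make_rng(100 + seed)
            reads = [apply_read_errors(truth, model, rng) for _ in range(60)]
            meta, drafts = iterate_consensus_with_drafts(
                reads, SamplePlan(20, 5, seed=seed)
            )
            pol = polish(meta, reads)
            draft_idents.append(np.median([identity(d, truth) for d in drafts]))
            polished_idents.append(identity(pol.sequence.upper(), truth))
        assert np.median(polished_idents) >= np.median(draft_idents)
        assert np.median(polished_idents) > 0.99


class TestPolish:
    def test_identical_reads_no_changes_full_support(self):
        cons = random_seq(1_000, make_rng(7))
        pol = polish(cons, [cons] * 20)
        assert pol.sequence == cons
        assert (pol.support == 1.0).all()
        assert (pol.coverage == 20).all()
        assert pol.average_coverage == 20

    def test_planted_consensus_error_corrected(self):
        truth = random_seq(1_000, make_rng(8))
        bad = truth[:500] + ("A" if truth[500] != "A" else "C") + truth[501:]
        pol = polish(bad, [truth] * 50)
        assert pol.sequence.upper() == truth

    def test_low_coverage_positions_removed(self):
        cons = random_seq(1_000, make_rng(9))
        # 40 full-length reads + 10 half-length: second half covered 40x,
        # first half 50x -> average 45, half-average 22.5; craft a region
        # covered by only 10 reads to fall below it
        reads = [cons] * 10 + [cons[:500]] * 40
        pol = polish(cons, reads)
        # positions 500.. are covered by 10 < 25 (=avg/2) -> removed
        assert len(pol.sequence) == 500
        assert pol.sequence == cons[:500]

    def test_weak_support_lowercase_masked(self):
        cons = random_seq(600, make_rng(10))
        i = 300
        variants = []
        for b in ("A", "C", "G", "T", "A", "C", "G", "T", "A", "C"):
            variants.append(cons[:i] + b + cons[i + 1 :])
        pol = polish(cons, variants)
        # at position i the best base has 3/10 support -> masked lowercase
        assert pol.sequence[i].islower()
        assert pol.sequence[:i].isupper()

    def test_no_reads_is_an_error(self):
        with pytest.raises(ValueError):
            polish("ACGT", [])


class TestShortreadPolish:
    def test_known_errors_fixed_at_high_coverage(self):
        truth = random_seq(4_000, make_rng(11))
        draft = list(truth)
        for pos in (400, 1_500, 2_700):
            draft[pos] = "A" if truth[pos] != "A" else "G"
        draft = "".join(draft)
        reads = [truth[i : i + 300] for i in range(0, 3_700, 25)]
        pol = shortread_polish(draft, reads, [(0, len(draft))])
        assert pol.sequence.upper() == truth

    def test_eighty_percent_support_boundary(self):
        truth = random_seq(2_000, make_rng(12))
        pos = 1_000
        alt = "A" if truth[pos] != "A" else "G"
        draft = truth[:pos] + alt + truth[pos + 1 :]
        window = [truth[pos - 150 : pos + 150]]
        alt_window = [draft[pos - 150 : pos + 150]]
        # 79/100 reads support the true base: below threshold, unchanged
        pol = shortread_polish(draft, window * 79 + alt_window * 21, [(0, len(draft))])
        assert pol.sequence[pos] == alt
        # 80/100: replaced
        pol = shortread_polish(draft, window * 80 + alt_window * 20, [(0, len(draft))])
        assert pol.sequence[pos] == truth[pos]

    def test_outside_unique_regions_untouched(self):
        truth = random_seq(2_000, make_rng(13))
        pos = 1_000
        alt = "A" if truth[pos] != "A" else "G"
        draft = truth[:pos] + alt + truth[pos + 1 :]
        reads = [truth[i : i + 300] for i in range(0, 1_700, 20)]
        pol = shortread_polish(draft, reads, [(0, 500)])
        assert pol.sequence[pos] == alt  # error site not in a unique region

    def test_zero_coverage_region_untouched(self):
        truth = random_seq(2_000, make_rng(14))
        draft = truth[:500] + "ACGT" * 10 + truth[540:]
        reads = [truth[1_000 + i : 1_300 + i] for i in range(0, 400, 40)]
        pol = shortread_polish(draft, reads, [(0, len(draft))])
        assert pol.sequence[500:540] == "ACGT" * 10
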