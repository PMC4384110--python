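import random

import pytest

from sandwichfold import (
    SearchParams,
    classify_batch,
    enumerate_candidate_assignments,
    enumerate_satisfying,
    explain,
    search,
)
from sandwichfold.errors import SequenceError
from sandwichfold.model import Geometry
from sandwichfold.synth import generate_random, positive_biased_composition

from conftest import flat_oracle


def compositions_in_range(total, parts, lo, hi):
    """Brute-force count of compositions of `total` into `parts` parts in [lo,hi]."""
    if parts == 1:
        return 1 if lo <= total <= hi else 0
    return sum(
        compositions_in_range(total - x, parts - 1, lo, hi)
        for x in range(lo, min(hi, total) + 1)
    )


class TestCandidateEnumeration:
    def test_too_short_is_empty(self, rs):
        assert list(enumerate_candidate_assignments(71, rs.geometry)) == []

    def test_length_72_counts_compositions(self, rs):
        cands = list(enumerate_candidate_assignments(72, rs.geometry))
        assert all(a.strand_starts[0] == 0 for a in cands)
        assert all(sum(a.loop_lengths()) == 30 for a in cands)
        assert len(cands) == compositions_in_range(30, 6, 3, 16)

    def test_total_range_disabled_same_at_72_with_no_tails(self, rs):
        from dataclasses import replace

        # without tails the length alone forces the loop total to 30;
        # with unbounded tails disabling the range admits shorter loops
        g0 = replace(rs.geometry, max_n_tail=0, max_c_tail=0)
        g1 = replace(g0, loop_total_range=None)
        with_total = list(enumerate_candidate_assignments(72, g0))
        without = list(enumerate_candidate_assignments(72, g1))
        assert with_total == without
        free_tails = replace(rs.geometry, loop_total_range=None)
        superset = {
            a.strand_starts
            for a in enumerate_candidate_assignments(72, free_tails)
        }
        assert {a.strand_starts for a in with_total} <= superset

    def test_lexicographic_order(self, rs):
        cands = [a.strand_starts for a in enumerate_candidate_assignments(74, rs.geometry)]
        assert cands == sorted(cands)
        assert len(cands) == len(set(cands))

    def test_exhaustive_against_independent_enumeration(self, rs):
        g = rs.geometry
        L = 75

        def loop_tuples(parts, remaining_max):
            """All tuples of `parts` loop lengths in [3,16] with sum <= remaining_max."""
            if parts == 0:
                yield ()
                return
            for x in range(3, min(16, remaining_max) + 1):
                for rest in loop_tuples(parts - 1, remaining_max - x):
                    yield (x,) + rest

        expected = []
        for start in range(L):
            budget = L - start - 42  # residues available for loops + C tail
            if budget < 30:
                break
            for loops in loop_tuples(6, min(60, budget)):
                if sum(loops) < 30:
                    continue
                starts = [start]
                for ln in loops:
                    starts.append(starts[-1] + 6 + ln)
                expected.append(tuple(starts))
        got = [a.strand_starts for a in enumerate_candidate_assignments(L, g)]
        assert got == sorted(expected)

    def test_tail_caps_respected(self, rs):
        from dataclasses import replace

        g = replace(rs.geometry, max_n_tail=1, max_c_tail=0)
        for a in enumerate_candidate_assignments(76, g):
            assert a.n_tail <= 1
            assert a.c_tail() == 0


class TestSearch:
    def test_worked_positive(self, rs, worked_seq):
        d = search(worked_seq, rs)
        assert d.accepted
        assert d.witness.strand_starts_1based() == (1, 12, 23, 34, 45, 56, 67)

    def test_n_tail_absorbed(self, rs, worked_seq):
        d = search("MST" + worked_seq, rs)
        assert d.accepted
        assert d.witness.strand_starts_1based()[0] == 4

    def test_polyg_rejected(self, rs):
        assert not search("G" * 100, rs).accepted

    def test_lowercase_and_whitespace_ok(self, rs, worked_seq):
        assert search(worked_seq.lower() + "\n", rs).accepted

    def test_strict_alphabet(self, rs, worked_seq):
        seq = "X" + worked_seq
        assert search(seq, rs).accepted  # X absorbed into the N tail
        with pytest.raises(SequenceError):
            search(seq, rs, SearchParams(strict_alphabet=True))

    def test_junk_characters_always_rejected(self, rs):
        with pytest.raises(SequenceError):
            search("VQV1ASQ", rs)

    def test_enumerate_all_counts(self, rs, worked_seq):
        d = search(worked_seq, rs, SearchParams(enumerate_all=True, max_witnesses=5))
        assert d.accepted and d.n_satisfying == 1
        assert d.witnesses == (d.witness,)

    def test_witness_matches_enumeration(self, rs, worked_seq):
        sats = enumerate_satisfying(worked_seq, rs)
        assert sats and sats[0] == search(worked_seq, rs).witness

    def test_oracle_guard(self, rs):
        with pytest.raises(SequenceError, match="guard"):
            enumerate_satisfying("V" * 600, rs)

    def test_too_short_empty(self, rs):
        assert enumerate_satisfying("V" * 71, rs) == []
        assert not search("V" * 71, rs).accepted


class TestOracleEquivalence:
    """search() vs the flat brute-force oracle (structural enumeration +
    per-candidate check) and vs enumerate_satisfying, pruned and unpruned.

    The flat oracle checks every one of the ~6000 candidates individually,
    so it only runs at the minimum sequence length; the engine-level
    exhaustive route covers longer sequences.
    """

    @pytest.mark.parametrize("seed", range(6))
    def test_random_minimum_length(self, rs, seed):
        comp = (
            "uniform" if seed % 2 == 0 else positive_biased_composition(seed=1)
        )
        seq = generate_random((72, 72), comp, seed=seed).sequence
        oracle = flat_oracle(seq, rs)
        fast = search(seq, rs)
        slow = enumerate_satisfying(seq, rs)
        unpruned = search(seq, rs, SearchParams(pruning=False))
        assert slow == oracle
        assert fast.accepted == unpruned.accepted == bool(oracle)
        if oracle:
            assert fast.witness == unpruned.witness == oracle[0]

    @pytest.mark.parametrize("seed", range(20))
    def test_longer_sequences_pruned_vs_exhaustive(self, rs, seed):
        comp = (
            "uniform" if seed % 2 == 0 else positive_biased_composition(seed=1)
        )
        seq = generate_random((72, 120), comp, seed=seed).sequence
        slow = enumerate_satisfying(seq, rs)
        fast = search(seq, rs)
        unpruned = search(seq, rs, SearchParams(pruning=False))
        assert fast.accepted == unpruned.accepted == bool(slow)
        if slow:
            assert fast.witness == unpruned.witness == slow[0]

    def test_worked_positive_oracle(self, rs, worked_seq):
        oracle = flat_oracle(worked_seq, rs)
        assert oracle == enumerate_satisfying(worked_seq, rs)
        assert oracle[0] == search(worked_seq, rs).witness

    @pytest.mark.parametrize("seed", range(3))
    def test_near_positive_mutants(self, rs, seed):
        from sandwichfold.synth import generate_positive

        rng = random.Random(seed)
        pos = generate_positive(seed=seed)  # default params: length 72
        seq = list(pos.sequence)
        for _ in range(3):
            seq[rng.randrange(len(seq))] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(seq)
        oracle = flat_oracle(seq, rs)
        assert enumerate_satisfying(seq, rs) == oracle
        d = search(seq, rs)
        assert d.accepted == bool(oracle)
        if oracle:
            assert d.witness == oracle[0]


class TestInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_tail_extension_preserves_acceptance(self, rs, seed):
        from sandwichfold.synth import generate_positive

        pos = generate_positive(seed=seed)
        assert search(pos.sequence, rs).accepted
        assert search("M" * 4 + pos.sequence, rs).accepted
        assert search(pos.sequence + "W" * 6, rs).accepted

    def test_monotone_in_rules(self, rs, worked_seq):
        # a satisfiable sequence under the full set stays satisfiable under
        # any group subset
        for groups in ({"T1"}, {"T2", "T3"}, {"T1", "T3", "LOOPS"}):
            assert search(worked_seq, rs.subset(groups)).accepted

    def test_deterministic(self, rs, worked_seq):
        a = search(worked_seq, rs)
        b = search(worked_seq, rs)
        assert a == b


class TestExplain:
    def test_accept_has_no_best_failing(self, rs, worked_seq):
        d = explain(worked_seq, rs)
        assert d.accepted and d.best_failing is None

    def test_mutated_interlock_cites_pro_rules(self, rs, worked_seq):
        # strand 2 window V -> P (position 13 of the window start 11)
        seq = worked_seq[:13] + "P" + worked_seq[14:]
        d = explain(seq, rs)
        assert not d.accepted
        assignment, report = d.best_failing
        ids = set(report.rule_ids())
        assert ids & {"t1r7", "t2r3", "t3r7", "t3r6", "t3r9"}

    def test_best_failing_is_minimal(self, rs, worked_seq):
        from sandwichfold.model import check_assignment

        seq = worked_seq[:13] + "P" + worked_seq[14:]
        d = explain(seq, rs)
        best_a, best_report = d.best_failing
        counts = [
            len(check_assignment(seq, a, rs).entries)
            for a in enumerate_candidate_assignments(len(seq), rs.geometry)
        ]
        assert len(best_report.entries) == min(counts)

    def test_polyg_cites_gly_rules(self, rs):
        d = explain("G" * 80, rs)
        assert not d.accepted
        ids = set(d.best_failing[1].rule_ids())
        assert {"t1r8", "t3r8"} & ids

    def test_too_short_has_no_candidates(self, rs):
        d = explain("G" * 20, rs)
        assert not d.accepted and d.best_failing is None


class TestClassifyBatch:
    def test_mixed_batch(self, rs, worked_seq):
        records = [("pos", worked_seq), ("neg", "G" * 80)]
        results = classify_batch(records, rs)
        assert [r.id for r in results] == ["pos", "neg"]
        assert results[0].decision.accepted
        assert not results[1].decision.accepted

    def test_empty_batch(self, rs):
        assert classify_batch([], rs) == []

    def test_duplicate_ids_both_processed(self, rs, worked_seq, caplog):
        records = [("a", worked_seq), ("a", worked_seq)]
        results = classify_batch(records, rs)
        assert len(results) == 2

    def test_bad_record_does_not_abort(self, rs, worked_seq):
        records = [("bad", "VQ#"), ("good", worked_seq)]
        results = classify_batch(records, rs)
        assert results[0].error is not None
        assert results[1].decision.accepted


class TestGeometryVariants:
    def test_even_in_parity_flips_decision(self, rs, worked_seq):
        # the worked positive alternates V/Q starting hydrophobic; flipping
        # the face convention must not accept it at the same placement
        flipped = rs.geometry.with_parity("even-in")
        assert flipped.hydrophobic_positions == (2, 4, 6)

    def test_min_span(self, rs):
        assert rs.geometry.min_span() == 72
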