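import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sandwichfold import (
    Assignment,
    Bound,
    CountDescriptor,
    ResidueClass,
    Rule,
    RuleSet,
    check_assignment,
    check_loops,
    count_feature,
    default_ruleset,
    evaluate_rule,
    load_ruleset,
    loop_favorable_value,
)
from sandwichfold.errors import RuleConfigError
from sandwichfold.model import (
    FACE_ANY,
    FACE_HYDROPHILIC,
    FACE_HYDROPHOBIC,
    LOOP_RULE_IDS,
    Geometry,
)
from sandwichfold.residues import CLASSES

AA = "ACDEFGHIKLMNPQRSTVWY"


def descriptor(cls, face):
    return CountDescriptor(ResidueClass(cls, CLASSES[cls]), face)


def single_strand_count(window, cls, face):
    """Count on a minimal synthetic context with strand 1 = window."""
    g = Geometry()
    seq = window + "G" * 5 + ("VQVQVQ" + "G" * 5) * 5 + "VQVQVQ"
    a = Assignment(tuple(range(0, 77, 11)), len(seq))
    return count_feature(seq, a, descriptor(cls, face), g).per_strand[0]


class TestDefaultRuleSet:
    def test_group_sizes(self, rs):
        assert len(rs.rules_in_group("T1")) == 9
        assert len(rs.rules_in_group("T2")) == 5
        assert len(rs.rules_in_group("T3")) == 9
        assert len(rs.strand_rules) == 23
        assert rs.loop_rules is not None

    def test_every_rule_has_provenance(self, rs):
        for r in rs.strand_rules:
            assert r.provenance, r.id

    def test_t1r1_bounds(self, rs):
        r = rs.get_rule("t1r1")
        assert r.per_strand[2] == Bound(3, 3)
        assert r.per_strand[3] == Bound(3, 3)
        for k in (1, 4, 5, 6, 7):
            assert r.per_strand[k] == Bound(1, None)
        assert r.interlock_total == Bound(9, 12)
        assert r.non_interlock_total == Bound(4, 6)
        assert r.all_strands == Bound(13, 17)

    def test_gly_banned_from_core_positions(self, rs):
        r = rs.get_rule("t1r8")
        assert all(b == Bound(0, 0) for b in r.per_strand.values())
        assert r.all_strands == Bound(0, 0)

    def test_t3r3_aromatic_total(self, rs):
        assert rs.get_rule("t3r3").all_strands == Bound(2, 8)

    # the six notation/consistency decisions baked into the defaults
    def test_erratum_cys_total(self, rs):
        assert rs.get_rule("t1r4").all_strands == Bound(0, 2)

    def test_erratum_gly_hydrophilic_total(self, rs):
        r = rs.get_rule("t2r4")
        assert r.interlock_total == Bound(0, 2)
        assert r.all_strands == Bound(0, 2)

    def test_erratum_charged_non_interlock_scope(self, rs):
        r = rs.get_rule("t1r9")
        assert rs.geometry.non_interlock_strands == (1, 4, 7)
        for k in (1, 4, 7):
            assert r.per_strand[k] == Bound(0, 2)
        assert r.non_interlock_total == Bound(0, 3)

    def test_erratum_hydrophobic_core_total_from_row(self, rs):
        assert rs.get_rule("t1r1").all_strands == Bound(13, 17)

    def test_erratum_pro_hydrophilic_strands(self, rs):
        r = rs.get_rule("t2r3")
        assert r.per_strand[2] == Bound(0, 0)
        assert r.per_strand[3] == Bound(0, 0)
        assert r.per_strand[6] == Bound(0, 0)
        assert r.per_strand[5] == Bound(0, 1)

    def test_erratum_six_loops_with_shared_cap(self, rs):
        assert rs.geometry.n_loops == 6
        assert rs.loop_rules.total_loop_hydrophobic_max == 12

    def test_loop_rule_ids_fixed(self):
        assert LOOP_RULE_IDS == (
            "loop_favorability",
            "loop_hydrophobic_majority",
            "loop_hydrophobic_total",
            "loop_length",
        )

    def test_unique_ids_and_groups(self, rs):
        ids = [r.id for r in rs.strand_rules]
        assert len(ids) == len(set(ids))
        assert set(r.group for r in rs.strand_rules) == {"T1", "T2", "T3"}

    def test_deterministic(self):
        a, b = default_ruleset(), default_ruleset()
        assert a.provenance_hash() == b.provenance_hash()


class TestCountFeature:
    def test_hydrophobic_positions_simple(self):
        assert single_strand_count("VQVQVQ", "HYDROPHOBIC", FACE_HYDROPHOBIC) == 3

    def test_hydrophilic_positions_excludes_ala(self):
        assert single_strand_count("VQVASQ", "HYDROPHILIC", FACE_HYDROPHILIC) == 2

    def test_worked_sequence_totals(self, rs, worked_seq, worked_assignment):
        counts = count_feature(
            worked_seq, worked_assignment,
            descriptor("HYDROPHOBIC", FACE_HYDROPHOBIC), rs.geometry,
        )
        assert counts.interlock_total == 12
        assert counts.non_interlock_total == 4
        assert counts.all_total == 16

    def test_loops_face(self, rs, worked_seq, worked_assignment):
        counts = count_feature(
            worked_seq, worked_assignment, descriptor("GLY", "loops"), rs.geometry
        )
        assert counts.per_loop == (5, 5, 5, 5, 5, 5)
        assert counts.total == 30

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_scan(self, seed):
        rng = random.Random(seed)
        g = Geometry()
        lens = [rng.randint(3, 8) for _ in range(6)]
        seq_parts, starts, pos = [], [], 0
        for i in range(7):
            starts.append(pos)
            seq_parts.append("".join(rng.choice(AA) for _ in range(6)))
            pos += 6
            if i < 6:
                seq_parts.append("".join(rng.choice(AA) for _ in range(lens[i])))
                pos += lens[i]
        seq = "".join(seq_parts)
        a = Assignment(tuple(starts), len(seq))
        cls = rng.choice(sorted(CLASSES))
        face = rng.choice([FACE_HYDROPHOBIC, FACE_HYDROPHILIC, FACE_ANY])
        counts = count_feature(seq, a, descriptor(cls, face), g)
        # naive recount straight off the definition
        offsets = g.face_offsets(face)
        naive = [
            sum(1 for o in offsets if seq[w + o] in CLASSES[cls])
            for w in starts
        ]
        assert list(counts.per_strand) == naive
        assert counts.all_total == sum(naive)
        assert counts.interlock_total == naive[1] + naive[2] + naive[4] + naive[5]
        assert counts.non_interlock_total == naive[0] + naive[3] + naive[6]
        assert counts.interlock_total + counts.non_interlock_total == counts.all_total


class TestEvaluateRule:
    def test_zero_counts_meet_zero_bounds(self, rs, worked_assignment):
        seq = "V" * 72
        counts = count_feature(
            seq, worked_assignment, rs.get_rule("t1r8").descriptor, rs.geometry
        )
        assert evaluate_rule(counts, rs.get_rule("t1r8")) == []

    def test_exact_bound_violation(self, rs, worked_seq, worked_assignment):
        shifted = Assignment(
            (0, 12, 22, 33, 44, 55, 66), len(worked_seq)
        )  # strand 2 one step right, into the loop glycines
        counts = count_feature(
            worked_seq, shifted, rs.get_rule("t1r1").descriptor, rs.geometry
        )
        entries = evaluate_rule(counts, rs.get_rule("t1r1"))
        strand2 = [e for e in entries if e.scope == "strand_2"]
        assert strand2 and strand2[0].observed < 3

    def test_all_strands_violation(self, rs):
        seq = ("AQAQAQ" + "G" * 5) * 6 + "AQAQAQ"
        a = Assignment(tuple(range(0, 67, 11)), len(seq))
        counts = count_feature(seq, a, rs.get_rule("t3r2").descriptor, rs.geometry)
        entries = evaluate_rule(counts, rs.get_rule("t3r2"))
        assert any(e.scope == "all" and e.observed > 4 for e in entries)


class TestLoops:
    def test_favorable_values(self):
        assert loop_favorable_value("GPGPG") == 10
        assert loop_favorable_value("DNST") == 4
        assert loop_favorable_value("AAAA") == 0

    def test_clean_glycine_loops(self, rs, worked_seq, worked_assignment):
        assert check_loops(
            worked_seq, worked_assignment, rs.loop_rules, rs.geometry
        ) == []

    def test_hydrophobic_loop_fails_twice(self, rs):
        seq = (
            "VQVASQ" + "LVLVL" + "FQVAVQ" + "GGGGG" + "VQVAVQ" + "GGGGG"
            + "VQSQNQ" + "GGGGG" + "VQAQVK" + "GGGGG" + "VQCQVY" + "GGGGG"
            + "VQSQTE"
        )
        a = Assignment(tuple(range(0, 67, 11)), len(seq))
        entries = check_loops(seq, a, rs.loop_rules, rs.geometry)
        ids = {(e.rule_id, e.scope) for e in entries}
        assert ("loop_favorability", "loop_1") in ids
        assert ("loop_hydrophobic_majority", "loop_1") in ids

    def test_short_total_flagged(self, rs):
        # six loops of 4 residues: total 24 < 30
        seq = ("VQVASQ" + "GGGG") * 6 + "VQVASQ"
        a = Assignment(tuple(range(0, 61, 10)), len(seq))
        entries = check_loops(seq, a, rs.loop_rules, rs.geometry)
        assert any(
            e.rule_id == "loop_length" and e.scope == "loops" and e.observed == 24
            for e in entries
        )


class TestCheckAssignment:
    def test_worked_positive_satisfied(self, rs, worked_seq, worked_assignment):
        assert check_assignment(worked_seq, worked_assignment, rs).satisfied

    def test_polyg_never_satisfied(self, rs, worked_assignment):
        report = check_assignment("G" * 72, worked_assignment, rs)
        assert not report.satisfied
        assert "t1r8" in report.rule_ids()

    def test_adding_rules_never_removes_violations(self, rs, worked_seq):
        shifted = Assignment((0, 12, 22, 33, 44, 55, 66), len(worked_seq))
        t1_only = rs.subset({"T1"})
        v_small = set(check_assignment(worked_seq, shifted, t1_only).entries)
        v_full = set(check_assignment(worked_seq, shifted, rs).entries)
        assert v_small <= v_full

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_conservation_across_scopes(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice(AA) for _ in range(72))
        a = Assignment(tuple(range(0, 67, 11)), 72)
        g = Geometry()
        for cls in ("HYDROPHOBIC", "CHARGED", "GLY"):
            for face in (FACE_HYDROPHOBIC, FACE_HYDROPHILIC, FACE_ANY):
                c = count_feature(seq, a, descriptor(cls, face), g)
                assert c.interlock_total + c.non_interlock_total == c.all_total


class TestLoadRuleset:
    def test_empty_document_is_default(self, rs):
        assert load_ruleset({}).provenance_hash() == rs.provenance_hash()
        assert load_ruleset(None).provenance_hash() == rs.provenance_hash()

    def test_coefficient_override_only(self, rs):
        out = load_ruleset({"loop_rules": {"favorability_coefficient": 0.5}})
        assert out.loop_rules.favorability_coefficient == 0.5
        assert out.strand_rules == rs.strand_rules
        assert out.geometry == rs.geometry

    def test_min_greater_than_max_rejected(self):
        with pytest.raises(RuleConfigError, match="min > max"):
            load_ruleset({"rules": [{"id": "t1r1", "all": [5, 2]}]})

    def test_unknown_residue_letter_rejected(self):
        with pytest.raises(RuleConfigError, match="unknown residue"):
            load_ruleset(
                {"rules": [{"id": "x1", "residues": "VJ", "face": "any",
                            "group": "T3", "all": [0, 1]}]}
            )

    def test_unknown_strand_index_rejected(self):
        with pytest.raises(RuleConfigError, match="outside 1..7"):
            load_ruleset({"rules": [{"id": "t1r1", "per_strand": {"9": 1}}]})

    def test_duplicate_id_rejected(self):
        with pytest.raises(RuleConfigError, match="duplicate"):
            load_ruleset(
                {"rules": [{"id": "t1r1", "all": [0, 5]},
                           {"id": "t1r1", "all": [0, 6]}]}
            )

    def test_yaml_text_and_parity(self):
        out = load_ruleset("geometry:\n  parity: even-in\n")
        assert out.geometry.hydrophobic_positions == (2, 4, 6)

    def test_override_marks_user_provenance(self):
        out = load_ruleset({"rules": [{"id": "t1r1", "all": [10, 20]}]})
        r = out.get_rule("t1r1")
        assert r.provenance == "user"
        assert r.all_strands == Bound(10, 20)


class TestRuleSetSurgery:
    def test_subset_groups(self, rs):
        t13 = rs.subset({"T1", "T3"})
        assert len(t13.strand_rules) == 18
        assert t13.loop_rules is None
        assert rs.subset({"T1", "LOOPS"}).loop_rules is not None

    def test_subset_unknown_group(self, rs):
        with pytest.raises(RuleConfigError):
            rs.subset({"T9"})

    def test_bad_bound_rejected_at_construction(self):
        with pytest.raises(RuleConfigError):
            Bound(5, 2)

    def test_duplicate_rule_ids_rejected(self, rs):
        with pytest.raises(RuleConfigError):
            RuleSet(strand_rules=(rs.strand_rules[0],) * 2)
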