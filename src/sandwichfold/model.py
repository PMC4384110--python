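"""Strand/loop geometry, count-constraint rules and pure rule evaluation.

The fold grammar is a list of :class:`Rule` objects.  Each rule counts the
residues of one class at one *face* of the seven 6-residue strand windows
(core-facing positions, surface-facing positions, or any position) and
constrains the counts per strand, over the interlock strands (2, 3, 5, 6),
over the non-interlock strands (1, 4, 7) and over all strands.  Loop
placements are constrained separately through :class:`LoopRules`.

Everything in this module is pure: given a sequence and a fixed
:class:`Assignment`, rule evaluation is deterministic and side-effect free.
The search over assignments lives in :mod:`sandwichfold.search`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import AssignmentError, RuleConfigError
from .residues import AMINO_ACIDS, CLASSES, LOOP_WEIGHTS, class_members

FACE_HYDROPHOBIC = "hydrophobic_positions"
FACE_HYDROPHILIC = "hydrophilic_positions"
FACE_ANY = "any_position"
FACE_LOOPS = "loops"
FACES = (FACE_HYDROPHOBIC, FACE_HYDROPHILIC, FACE_ANY, FACE_LOOPS)

GROUPS = ("T1", "T2", "T3", "LOOPS")

LOOP_RULE_IDS = (
    "loop_favorability",
    "loop_hydrophobic_majority",
    "loop_hydrophobic_total",
    "loop_length",
)


# ---------------------------------------------------------------------------
# bounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bound:
    """Closed integer interval; ``hi=None`` means unbounded above."""

    lo: int = 0
    hi: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise RuleConfigError(f"bound minimum must be >= 0, got {self.lo}")
        if self.hi is not None and self.hi < self.lo:
            raise RuleConfigError(f"bound [{self.lo},{self.hi}] has min > max")

    def contains(self, n: int) -> bool:
        return n >= self.lo and (self.hi is None or n <= self.hi)

    def __contains__(self, n: int) -> bool:  # pragma: no cover - sugar
        return self.contains(n)

    def __str__(self) -> str:
        hi = "inf" if self.hi is None else str(self.hi)
        return f"[{self.lo},{hi}]"


def exactly(n: int) -> Bound:
    return Bound(n, n)


def at_most(n: int) -> Bound:
    return Bound(0, n)


def at_least(n: int) -> Bound:
    return Bound(n, None)


def between(lo: int, hi: int) -> Bound:
    return Bound(lo, hi)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Skeleton of the fold: seven 6-residue strands joined by six loops.

    Strand positions are 1-based within a strand window.  By default the odd
    positions (1, 3, 5) face the core and the even positions the surface;
    ``parity='even-in'`` flips the convention globally.
    """

    n_strands: int = 7
    strand_length: int = 6
    interlock_strands: tuple[int, ...] = (2, 3, 5, 6)
    non_interlock_strands: tuple[int, ...] = (1, 4, 7)
    hydrophobic_positions: tuple[int, ...] = (1, 3, 5)
    hydrophilic_positions: tuple[int, ...] = (2, 4, 6)
    loop_len_range: tuple[int, int] = (3, 16)
    loop_total_range: Optional[tuple[int, int]] = (30, 60)
    max_n_tail: Optional[int] = None
    max_c_tail: Optional[int] = None

    def __post_init__(self) -> None:
        pos = set(self.hydrophobic_positions) | set(self.hydrophilic_positions)
        if pos != set(range(1, self.strand_length + 1)) or (
            set(self.hydrophobic_positions) & set(self.hydrophilic_positions)
        ):
            raise RuleConfigError(
                "hydrophobic and hydrophilic positions must partition "
                f"1..{self.strand_length}"
            )
        if self.loop_len_range[0] > self.loop_len_range[1]:
            raise RuleConfigError("loop_len_range has min > max")
        if self.loop_total_range and self.loop_total_range[0] > self.loop_total_range[1]:
            raise RuleConfigError("loop_total_range has min > max")
        if set(self.interlock_strands) & set(self.non_interlock_strands):
            raise RuleConfigError("interlock/non-interlock strand sets overlap")

    @property
    def n_loops(self) -> int:
        return self.n_strands - 1

    def face_offsets(self, face: str) -> tuple[int, ...]:
        """0-based offsets within a strand window for a face."""
        if face == FACE_ANY:
            return tuple(range(self.strand_length))
        if face == FACE_HYDROPHOBIC:
            return tuple(p - 1 for p in self.hydrophobic_positions)
        if face == FACE_HYDROPHILIC:
            return tuple(p - 1 for p in self.hydrophilic_positions)
        raise ValueError(f"face {face!r} has no strand offsets")

    def min_loop_total(self) -> int:
        lo = self.n_loops * self.loop_len_range[0]
        if self.loop_total_range:
            lo = max(lo, self.loop_total_range[0])
        return lo

    def max_loop_total(self) -> int:
        hi = self.n_loops * self.loop_len_range[1]
        if self.loop_total_range:
            hi = min(hi, self.loop_total_range[1])
        return hi

    def min_span(self) -> int:
        """Shortest sequence that can host a full assignment (no tails)."""
        return self.n_strands * self.strand_length + self.min_loop_total()

    def with_parity(self, parity: str) -> "Geometry":
        """Return a geometry with the requested face parity.

        ``'odd-in'`` keeps positions 1,3,5 core-facing; ``'even-in'`` flips.
        """
        if parity not in ("odd-in", "even-in"):
            raise RuleConfigError(f"unknown parity {parity!r}")
        odd = tuple(p for p in range(1, self.strand_length + 1) if p % 2 == 1)
        even = tuple(p for p in range(1, self.strand_length + 1) if p % 2 == 0)
        if parity == "odd-in":
            return replace(self, hydrophobic_positions=odd, hydrophilic_positions=even)
        return replace(self, hydrophobic_positions=even, hydrophilic_positions=odd)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Assignment:
    """Placement of the strand skeleton onto a sequence.

    ``strand_starts`` are 0-based offsets of the seven strand windows, in
    ascending order.  Loop lengths and tails are implied by the starts and the
    sequence length.
    """

    strand_starts: tuple[int, ...]
    sequence_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand_starts", tuple(self.strand_starts))

    @property
    def n_tail(self) -> int:
        return self.strand_starts[0]

    def c_tail(self, strand_length: int = 6) -> int:
        return self.sequence_length - (self.strand_starts[-1] + strand_length)

    def loop_lengths(self, strand_length: int = 6) -> tuple[int, ...]:
        s = self.strand_starts
        return tuple(s[i + 1] - (s[i] + strand_length) for i in range(len(s) - 1))

    def windows(self, strand_length: int = 6) -> tuple[tuple[int, int], ...]:
        """0-based half-open [start, end) spans of the strand windows."""
        return tuple((w, w + strand_length) for w in self.strand_starts)

    def loops(self, strand_length: int = 6) -> tuple[tuple[int, int], ...]:
        """0-based half-open spans of the inter-strand loops."""
        s = self.strand_starts
        return tuple(
            (s[i] + strand_length, s[i + 1]) for i in range(len(s) - 1)
        )

    def strand_starts_1based(self) -> tuple[int, ...]:
        return tuple(w + 1 for w in self.strand_starts)

    def validate(self, geometry: Geometry) -> None:
        """Raise :class:`AssignmentError` unless the placement is well formed."""
        g = geometry
        s = self.strand_starts
        if len(s) != g.n_strands:
            raise AssignmentError(
                f"expected {g.n_strands} strand starts, got {len(s)}"
            )
        if s[0] < 0:
            raise AssignmentError("strand 1 starts before the sequence")
        if g.max_n_tail is not None and self.n_tail > g.max_n_tail:
            raise AssignmentError(f"N-tail {self.n_tail} exceeds cap {g.max_n_tail}")
        ct = self.c_tail(g.strand_length)
        if ct < 0:
            raise AssignmentError("strand 7 extends past the end of the sequence")
        if g.max_c_tail is not None and ct > g.max_c_tail:
            raise AssignmentError(f"C-tail {ct} exceeds cap {g.max_c_tail}")
        lens = self.loop_lengths(g.strand_length)
        lo, hi = g.loop_len_range
        for i, ln in enumerate(lens, start=1):
            if ln < lo or ln > hi:
                raise AssignmentError(
                    f"loop {i} length {ln} outside [{lo},{hi}]"
                )
        if g.loop_total_range:
            tlo, thi = g.loop_total_range
            if not tlo <= sum(lens) <= thi:
                raise AssignmentError(
                    f"total loop length {sum(lens)} outside [{tlo},{thi}]"
                )


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueClass:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.members) - AMINO_ACIDS
        if bad:
            raise RuleConfigError(
                f"residue class {self.name!r} has non-standard letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class CountDescriptor:
    """What to count: a residue class at one face of the strands (or loops)."""

    residue_class: ResidueClass
    face: str

    def __post_init__(self) -> None:
        if self.face not in FACES:
            raise RuleConfigError(f"unknown face {self.face!r}")


@dataclass(frozen=True)
class Rule:
    """One count-constraint row of the grammar.

    Absent bounds (``None`` aggregate, missing strand key) are unconstrained.
    """

    id: str
    group: str
    descriptor: CountDescriptor
    per_strand: Mapping[int, Bound] = field(default_factory=dict)
    interlock_total: Optional[Bound] = None
    non_interlock_total: Optional[Bound] = None
    all_strands: Optional[Bound] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_strand", dict(self.per_strand))
        bad = set(self.per_strand) - set(range(1, 8))
        if bad:
            raise RuleConfigError(
                f"rule {self.id!r}: strand keys {sorted(bad)} outside 1..7"
            )
        if self.group not in GROUPS:
            raise RuleConfigError(f"rule {self.id!r}: unknown group {self.group!r}")


@dataclass(frozen=True)
class LoopRules:
    """Constraints on the six inter-strand loops."""

    favorability_weights: Mapping[str, int] = field(
        default_factory=lambda: dict(LOOP_WEIGHTS)
    )
    favorability_coefficient: float = 2.0
    per_loop_hydrophobic_lt_hydrophilic: bool = True
    total_loop_hydrophobic_max: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "favorability_weights", dict(self.favorability_weights)
        )
        if any(w < 0 for w in self.favorability_weights.values()):
            raise RuleConfigError("loop favorability weights must be non-negative")
        if self.favorability_coefficient <= 0:
            raise RuleConfigError("favorability coefficient must be > 0")


@dataclass(frozen=True)
class RuleSet:
    """The full grammar: geometry + strand rules + loop rules."""

    geometry: Geometry = field(default_factory=Geometry)
    strand_rules: tuple[Rule, ...] = ()
    loop_rules: Optional[LoopRules] = field(default_factory=LoopRules)
    name: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand_rules", tuple(self.strand_rules))
        ids = [r.id for r in self.strand_rules]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RuleConfigError(f"duplicate rule ids {dup}")

    def groups(self) -> tuple[str, ...]:
        present = {r.group for r in self.strand_rules}
        if self.loop_rules is not None:
            present.add("LOOPS")
        return tuple(g for g in GROUPS if g in present)

    def rules_in_group(self, group: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.strand_rules if r.group == group)

    def get_rule(self, rule_id: str) -> Rule:
        for r in self.strand_rules:
            if r.id == rule_id:
                return r
        raise KeyError(f"no rule with id {rule_id!r}")

    def subset(self, groups: Iterable[str], name: Optional[str] = None) -> "RuleSet":
        """Keep only the rules of the named groups (geometry unchanged)."""
        groups = set(groups)
        unknown = groups - set(GROUPS)
        if unknown:
            raise RuleConfigError(f"unknown rule groups {sorted(unknown)}")
        return RuleSet(
            geometry=self.geometry,
            strand_rules=tuple(r for r in self.strand_rules if r.group in groups),
            loop_rules=self.loop_rules if "LOOPS" in groups else None,
            name=name or "+".join(sorted(groups)),
        )

    def with_rule(self, rule: Rule, name: Optional[str] = None) -> "RuleSet":
        """Replace the rule with the same id (or append a new one)."""
        out = []
        replaced = False
        for r in self.strand_rules:
            if r.id == rule.id:
                out.append(rule)
                replaced = True
            else:
                out.append(r)
        if not replaced:
            out.append(rule)
        return RuleSet(
            geometry=self.geometry,
            strand_rules=tuple(out),
            loop_rules=self.loop_rules,
            name=name or self.name,
        )

    def to_dict(self) -> dict:
        g = self.geometry

        def bd(b: Optional[Bound]):
            return None if b is None else [b.lo, b.hi]

        return {
            "name": self.name,
            "geometry": {
                "n_strands": g.n_strands,
                "strand_length": g.strand_length,
                "interlock_strands": list(g.interlock_strands),
                "non_interlock_strands": list(g.non_interlock_strands),
                "hydrophobic_positions": list(g.hydrophobic_positions),
                "hydrophilic_positions": list(g.hydrophilic_positions),
                "loop_len_range": list(g.loop_len_range),
                "loop_total_range": (
                    list(g.loop_total_range) if g.loop_total_range else None
                ),
                "max_n_tail": g.max_n_tail,
                "max_c_tail": g.max_c_tail,
            },
            "rules": [
                {
                    "id": r.id,
                    "group": r.group,
                    "class": r.descriptor.residue_class.name,
                    "residues": "".join(sorted(r.descriptor.residue_class.members)),
                    "face": r.descriptor.face,
                    "per_strand": {str(k): bd(v) for k, v in sorted(r.per_strand.items())},
                    "interlock": bd(r.interlock_total),
                    "non_interlock": bd(r.non_interlock_total),
                    "all": bd(r.all_strands),
                    "provenance": r.provenance,
                }
                for r in self.strand_rules
            ],
            "loop_rules": None
            if self.loop_rules is None
            else {
                "favorability_weights": dict(
                    sorted(self.loop_rules.favorability_weights.items())
                ),
                "favorability_coefficient": self.loop_rules.favorability_coefficient,
                "per_loop_hydrophobic_lt_hydrophilic": (
                    self.loop_rules.per_loop_hydrophobic_lt_hydrophilic
                ),
                "total_loop_hydrophobic_max": self.loop_rules.total_loop_hydrophobic_max,
            },
        }

    def provenance_hash(self) -> str:
        """Stable hash of the rule-set content, logged with every run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# violations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One violated bound: which rule, where, what was seen."""

    rule_id: str
    scope: str  # "strand_k" | "interlock" | "non_interlock" | "all" | "loop_k" | "loops"
    observed: int
    bound: Bound

    def __str__(self) -> str:
        return f"{self.rule_id}@{self.scope}: observed {self.observed}, bound {self.bound}"


@dataclass(frozen=True)
class ViolationReport:
    entries: tuple[Violation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def satisfied(self) -> bool:
        return not self.entries

    def rule_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.rule_id not in seen:
                seen.append(e.rule_id)
        return tuple(seen)


# ---------------------------------------------------------------------------
# counting & evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureCounts:
    per_strand: tuple[int, ...]
    interlock_total: int
    non_interlock_total: int
    all_total: int


@dataclass(frozen=True)
class LoopCounts:
    per_loop: tuple[int, ...]
    total: int


def count_window(sequence: str, start: int, members: frozenset[str],
                 offsets: Sequence[int]) -> int:
    return sum(1 for o in offsets if sequence[start + o] in members)


def count_feature(sequence: str, assignment: Assignment,
                  descriptor: CountDescriptor, geometry: Geometry):
    """Count class members at the descriptor's face for a fixed assignment.

    Returns :class:`FeatureCounts` for strand faces, :class:`LoopCounts`
    for ``face='loops'``.  Non-standard letters are members of no class.
    """
    members = descriptor.residue_class.members
    if descriptor.face == FACE_LOOPS:
        per_loop = tuple(
            sum(1 for c in sequence[a:b] if c in members)
            for a, b in assignment.loops(geometry.strand_length)
        )
        return LoopCounts(per_loop=per_loop, total=sum(per_loop))
    offsets = geometry.face_offsets(descriptor.face)
    per_strand = tuple(
        count_window(sequence, w, members, offsets)
        for w in assignment.strand_starts
    )
    il = sum(per_strand[k - 1] for k in geometry.interlock_strands)
    nil = sum(per_strand[k - 1] for k in geometry.non_interlock_strands)
    return FeatureCounts(
        per_strand=per_strand,
        interlock_total=il,
        non_interlock_total=nil,
        all_total=sum(per_strand),
    )


def evaluate_rule(counts: FeatureCounts, rule: Rule) -> list[Violation]:
    """One violation entry per violated bound of the rule."""
    out: list[Violation] = []
    for k, b in sorted(rule.per_strand.items()):
        c = counts.per_strand[k - 1]
        if not b.contains(c):
            out.append(Violation(rule.id, f"strand_{k}", c, b))
    for scope, b, c in (
        ("interlock", rule.interlock_total, counts.interlock_total),
        ("non_interlock", rule.non_interlock_total, counts.non_interlock_total),
        ("all", rule.all_strands, counts.all_total),
    ):
        if b is not None and not b.contains(c):
            out.append(Violation(rule.id, scope, c, b))
    return out


def loop_favorable_value(fragment: str, weights: Optional[Mapping[str, int]] = None) -> int:
    """Sum of per-residue loop weights over a fragment."""
    w = LOOP_WEIGHTS if weights is None else weights
    return sum(w.get(c, 0) for c in fragment)


def check_loops(sequence: str, assignment: Assignment, loop_rules: LoopRules,
                geometry: Geometry) -> list[Violation]:
    """Evaluate the four loop rules for every loop of the assignment.

    Per loop: the favorable value must reach ``coefficient * length``, and
    strongly hydrophobic residues must be a strict minority.  Globally: at
    most ``total_loop_hydrophobic_max`` strongly hydrophobic residues over
    all loops, and loop lengths inside the geometry ranges.
    """
    strong = CLASSES["STRONG_HYDROPHOBIC"]
    lr = loop_rules
    out: list[Violation] = []
    lo, hi = geometry.loop_len_range
    total_strong = 0
    total_len = 0
    for i, (a, b) in enumerate(assignment.loops(geometry.strand_length), start=1):
        frag = sequence[a:b]
        n = len(frag)
        total_len += n
        if n < lo or n > hi:
            out.append(Violation("loop_length", f"loop_{i}", n, Bound(lo, hi)))
        fav = loop_favorable_value(frag, lr.favorability_weights)
        need = lr.favorability_coefficient * n
        if fav < need:
            # observed value vs the integral threshold it had to reach
            out.append(
                Violation("loop_favorability", f"loop_{i}", fav,
                          Bound(int(-(-need // 1)), None))
            )
        n_strong = sum(1 for c in frag if c in strong)
        total_strong += n_strong
        if lr.per_loop_hydrophobic_lt_hydrophilic and not n_strong < n - n_strong:
            out.append(
                Violation("loop_hydrophobic_majority", f"loop_{i}", n_strong,
                          Bound(0, (n - 1) // 2))
            )
    if total_strong > lr.total_loop_hydrophobic_max:
        out.append(
            Violation("loop_hydrophobic_total", "loops", total_strong,
                      Bound(0, lr.total_loop_hydrophobic_max))
        )
    if geometry.loop_total_range:
        tlo, thi = geometry.loop_total_range
        if not tlo <= total_len <= thi:
            out.append(Violation("loop_length", "loops", total_len, Bound(tlo, thi)))
    return out


def check_assignment(sequence: str, assignment: Assignment,
                     ruleset: RuleSet) -> ViolationReport:
    """Evaluate every rule of the set against a fixed assignment."""
    assignment.validate(ruleset.geometry)
    if assignment.sequence_length != len(sequence):
        raise AssignmentError(
            f"assignment built for length {assignment.sequence_length}, "
            f"sequence has length {len(sequence)}"
        )
    entries: list[Violation] = []
    for rule in ruleset.strand_rules:
        counts = count_feature(sequence, assignment, rule.descriptor, ruleset.geometry)
        entries.extend(evaluate_rule(counts, rule))
    if ruleset.loop_rules is not None:
        entries.extend(
            check_loops(sequence, assignment, ruleset.loop_rules, ruleset.geometry)
        )
    return ViolationReport(entries=tuple(entries))


# ---------------------------------------------------------------------------
# the default rule set
# ---------------------------------------------------------------------------

def _rule(rid, group, cls, face, per_strand, il, nil, allb, prov):
    return Rule(
        id=rid,
        group=group,
        descriptor=CountDescriptor(ResidueClass(cls, class_members(cls)), face),
        per_strand=per_strand,
        interlock_total=il,
        non_interlock_total=nil,
        all_strands=allb,
        provenance=prov,
    )


def default_ruleset() -> RuleSet:
    """Build the shipped grammar.

    Three groups of strand rules (T1: core-facing positions, T2:
    surface-facing positions, T3: any position) plus the loop rules.  Where
    the published row and its prose commentary disagree, the row value is
    used; those spots are flagged in the provenance notes.
    """
    E, M, L, B = exactly, at_most, at_least, between
    rules = [
        # ----- T1: residues at hydrophobic (core-facing) positions --------
        _rule("t1r1", "T1", "HYDROPHOBIC", FACE_HYDROPHOBIC,
              {2: E(3), 3: E(3), 5: L(1), 6: L(1), 1: L(1), 4: L(1), 7: L(1)},
              B(9, 12), B(4, 6), B(13, 17),
              "T1 row 1: hydrophobic residues at core positions"),
        _rule("t1r2", "T1", "STRONG_HYDROPHOBIC", FACE_HYDROPHOBIC,
              {2: L(1), 3: L(1), 5: L(1), 6: L(1)},
              B(6, 10), B(2, 5), B(8, 15),
              "T1 row 2: strongly hydrophobic subset at core positions"),
        _rule("t1r3", "T1", "ALA", FACE_HYDROPHOBIC,
              {k: M(1) for k in range(1, 8)},
              M(2), M(2), M(2),
              "T1 row 3: Ala at core positions"),
        _rule("t1r4", "T1", "CYS", FACE_HYDROPHOBIC,
              {k: M(1) for k in range(1, 8)},
              M(2), M(2), M(2),
              "T1 row 4: Cys at core positions; grand total 2 per the row "
              "(commentary text says 3; row value kept)"),
        _rule("t1r5", "T1", "TYR", FACE_HYDROPHOBIC,
              {k: M(1) for k in range(1, 8)},
              M(1), M(1), M(2),
              "T1 row 5: Tyr at core positions"),
        _rule("t1r6", "T1", "AROMATIC", FACE_HYDROPHOBIC,
              {2: M(2), 3: M(2), 5: M(2), 6: M(2), 1: M(1), 4: M(1), 7: M(1)},
              M(3), M(1), M(3),
              "T1 row 6: aromatic residues at core positions"),
        _rule("t1r7", "T1", "PRO", FACE_HYDROPHOBIC,
              {2: E(0), 3: E(0), 5: E(0), 6: E(0), 1: M(1), 4: M(1), 7: M(1)},
              E(0), M(1), M(1),
              "T1 row 7: Pro at core positions"),
        _rule("t1r8", "T1", "GLY", FACE_HYDROPHOBIC,
              {k: E(0) for k in range(1, 8)},
              E(0), E(0), E(0),
              "T1 row 8: Gly excluded from core positions"),
        _rule("t1r9", "T1", "CHARGED", FACE_HYDROPHOBIC,
              {2: E(0), 3: E(0), 5: M(2), 6: M(2), 1: M(2), 4: M(2), 7: M(2)},
              M(2), M(3), M(4),
              "T1 row 9: charged residues at core positions; non-interlock "
              "scope is strands 1, 4, 7 (commentary lists 1, 3, 6 in error)"),
        # ----- T2: residues at hydrophilic (surface-facing) positions -----
        _rule("t2r1", "T2", "HYDROPHILIC", FACE_HYDROPHILIC,
              {k: L(1) for k in range(1, 8)},
              B(7, 10), B(5, 8), B(13, 18),
              "T2 row 1: hydrophilic residues at surface positions"),
        _rule("t2r2", "T2", "CHARGED", FACE_HYDROPHILIC,
              {},
              B(0, 5), B(0, 6), B(1, 9),
              "T2 row 2: charged residues at surface positions"),
        _rule("t2r3", "T2", "PRO", FACE_HYDROPHILIC,
              {2: E(0), 3: E(0), 5: M(1), 6: E(0), 1: M(1), 4: M(1), 7: M(1)},
              M(1), M(2), M(2),
              "T2 row 3: Pro at surface positions; zero in strands 2, 3, 6 "
              "and at most one in strand 5, per the row"),
        _rule("t2r4", "T2", "GLY", FACE_HYDROPHILIC,
              {k: M(1) for k in range(1, 8)},
              M(2), M(1), M(2),
              "T2 row 4: Gly at surface positions; grand total 2 (the row "
              "prints 1, below its own interlock subtotal of 2)"),
        _rule("t2r5", "T2", "PRO_GLY", FACE_HYDROPHILIC,
              {k: M(1) for k in range(1, 8)},
              M(3), M(2), M(3),
              "T2 row 5: Pro+Gly combined at surface positions"),
        # ----- T3: residues at any strand position ------------------------
        _rule("t3r1", "T3", "HYDROPHOBIC", FACE_ANY,
              {2: L(3), 3: L(3), 5: L(1), 6: L(2), 1: B(1, 4), 4: B(1, 4), 7: B(1, 4)},
              B(10, 18), B(5, 9), B(17, 26),
              "T3 row 1: hydrophobic residues anywhere in strands"),
        _rule("t3r2", "T3", "ALA", FACE_ANY,
              {2: M(1), 3: M(1), 5: M(2), 6: M(1), 1: M(2), 4: M(2), 7: M(2)},
              M(3), M(3), B(0, 4),
              "T3 row 2: Ala anywhere in strands"),
        _rule("t3r3", "T3", "AROMATIC", FACE_ANY,
              {2: M(2), 3: M(3), 5: M(2), 6: M(2), 1: M(2), 4: M(1), 7: M(2)},
              M(6), M(3), B(2, 8),
              "T3 row 3: aromatic residues anywhere in strands"),
        _rule("t3r4", "T3", "HYDROPHILIC", FACE_ANY,
              {2: L(1), 3: L(1), 5: L(1), 6: L(1), 1: B(2, 5), 4: B(2, 5), 7: B(2, 5)},
              B(8, 15), B(9, 13), B(18, 27),
              "T3 row 4: hydrophilic residues anywhere in strands"),
        _rule("t3r5", "T3", "CHARGED", FACE_ANY,
              {2: M(2), 3: M(3), 5: M(2), 6: M(2), 1: M(3), 4: M(4), 7: M(4)},
              B(1, 7), B(1, 7), B(1, 12),
              "T3 row 5: charged residues anywhere in strands"),
        _rule("t3r6", "T3", "DISRUPTOR5", FACE_ANY,
              {2: M(1), 3: M(3), 5: M(2), 6: M(2), 1: M(2), 4: M(4), 7: M(4)},
              M(5), B(2, 6), B(2, 10),
              "T3 row 6: Pro/Gly/Asn/Asp/Glu anywhere in strands"),
        _rule("t3r7", "T3", "PRO", FACE_ANY,
              {2: E(0), 3: E(0), 5: M(1), 6: E(0), 1: M(2), 4: M(2), 7: M(1)},
              M(1), B(0, 3), B(0, 3),
              "T3 row 7: Pro anywhere in strands"),
        _rule("t3r8", "T3", "GLY", FACE_ANY,
              {k: M(1) for k in range(1, 8)},
              M(2), B(0, 1), B(0, 2),
              "T3 row 8: Gly anywhere in strands"),
        _rule("t3r9", "T3", "PRO_GLY_ALA", FACE_ANY,
              {2: M(2), 3: M(1), 5: M(2), 6: M(1), 1: M(3), 4: M(2), 7: M(2)},
              M(4), B(1, 5), B(0, 6),
              "T3 row 9: Pro+Gly+Ala combined anywhere in strands"),
    ]
    return RuleSet(
        geometry=Geometry(),
        strand_rules=tuple(rules),
        loop_rules=LoopRules(),
        name="default",
    )


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def _parse_bound(value, where: str) -> Optional[Bound]:
    if value is None:
        return None
    if isinstance(value, int):
        return Bound(value, value)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        lo = 0 if value[0] is None else value[0]
        hi = value[1]
        if not isinstance(lo, int) or (hi is not None and not isinstance(hi, int)):
            raise RuleConfigError(f"{where}: bound entries must be integers or null")
        if hi is not None and hi < lo:
            raise RuleConfigError(f"{where}: bound [{lo},{hi}] has min > max")
        return Bound(lo, hi)
    raise RuleConfigError(f"{where}: expected integer or [min,max], got {value!r}")


def _parse_class(spec: dict, rid: str) -> ResidueClass:
    if "residues" in spec:
        letters = str(spec["residues"]).upper()
        bad = set(letters) - AMINO_ACIDS
        if bad:
            raise RuleConfigError(
                f"rule {rid!r}: unknown residue letters {sorted(bad)}"
            )
        return ResidueClass(spec.get("class", "custom"), frozenset(letters))
    cls = spec.get("class")
    if cls is None:
        raise RuleConfigError(f"rule {rid!r}: needs 'class' or 'residues'")
    if cls not in CLASSES:
        raise RuleConfigError(f"rule {rid!r}: unknown residue class {cls!r}")
    return ResidueClass(cls, class_members(cls))


def load_ruleset(document) -> RuleSet:
    """Build a rule set from an override document (dict, YAML text or path).

    Unspecified fields inherit the defaults; overridden/added rules are
    marked with ``provenance='user'``.
    """
    import yaml

    if document is None:
        doc: dict = {}
    elif isinstance(document, dict):
        doc = document
    else:
        text = document
        if hasattr(document, "read"):
            text = document.read()
        elif "\n" not in str(document) and str(document).endswith(
            (".yaml", ".yml", ".json")
        ):
            with open(document, "r", encoding="utf-8") as fh:
                text = fh.read()
        try:
            doc = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise RuleConfigError(f"cannot parse rule document: {exc}") from exc
    if not isinstance(doc, dict):
        raise RuleConfigError("rule document must be a mapping")

    base = default_ruleset()
    geometry = base.geometry
    gdoc = doc.get("geometry", {})
    if not isinstance(gdoc, dict):
        raise RuleConfigError("'geometry' must be a mapping")
    if "parity" in gdoc:
        geometry = geometry.with_parity(gdoc["parity"])
    simple = {}
    for key in ("loop_len_range", "loop_total_range"):
        if key in gdoc:
            v = gdoc[key]
            if v is not None:
                if not (isinstance(v, (list, tuple)) and len(v) == 2):
                    raise RuleConfigError(f"geometry.{key}: expected [min,max]")
                v = (int(v[0]), int(v[1]))
            simple[key] = v
    for key in ("max_n_tail", "max_c_tail"):
        if key in gdoc:
            v = gdoc[key]
            if v is not None and (not isinstance(v, int) or v < 0):
                raise RuleConfigError(f"geometry.{key}: expected null or int >= 0")
            simple[key] = v
    if simple:
        geometry = replace(geometry, **simple)

    loop_rules = base.loop_rules
    ldoc = doc.get("loop_rules", {})
    if ldoc is None:
        loop_rules = None
    elif isinstance(ldoc, dict):
        kwargs = {}
        for key in (
            "favorability_coefficient",
            "per_loop_hydrophobic_lt_hydrophilic",
            "total_loop_hydrophobic_max",
        ):
            if key in ldoc:
                kwargs[key] = ldoc[key]
        if "favorability_weights" in ldoc:
            w = dict(LOOP_WEIGHTS)
            for letter, weight in dict(ldoc["favorability_weights"]).items():
                letter = str(letter).upper()
                if letter not in AMINO_ACIDS:
                    raise RuleConfigError(
                        f"loop_rules.favorability_weights: unknown residue {letter!r}"
                    )
                w[letter] = int(weight)
            kwargs["favorability_weights"] = w
        loop_rules = LoopRules(
            **{
                "favorability_weights": dict(loop_rules.favorability_weights),
                "favorability_coefficient": loop_rules.favorability_coefficient,
                "per_loop_hydrophobic_lt_hydrophilic": (
                    loop_rules.per_loop_hydrophobic_lt_hydrophilic
                ),
                "total_loop_hydrophobic_max": loop_rules.total_loop_hydrophobic_max,
                **kwargs,
            }
        )
    else:
        raise RuleConfigError("'loop_rules' must be a mapping or null")

    rules = list(base.strand_rules)
    dropped = doc.get("drop_rules", [])
    if dropped:
        known = {r.id for r in rules}
        missing = set(dropped) - known
        if missing:
            raise RuleConfigError(f"drop_rules: unknown ids {sorted(missing)}")
        rules = [r for r in rules if r.id not in set(dropped)]

    rdoc = doc.get("rules", [])
    if not isinstance(rdoc, list):
        raise RuleConfigError("'rules' must be a list")
    seen_ids: set[str] = set()
    for spec in rdoc:
        if not isinstance(spec, dict) or "id" not in spec:
            raise RuleConfigError("each rule override needs an 'id'")
        rid = str(spec["id"])
        if rid in seen_ids:
            raise RuleConfigError(f"duplicate rule id {rid!r} in document")
        seen_ids.add(rid)
        existing = next((r for r in rules if r.id == rid), None)
        if existing is not None:
            rc = (
                _parse_class(spec, rid)
                if ("class" in spec or "residues" in spec)
                else existing.descriptor.residue_class
            )
            face = spec.get("face", existing.descriptor.face)
            group = spec.get("group", existing.group)
            per_strand = dict(existing.per_strand)
            il, nil, allb = (
                existing.interlock_total,
                existing.non_interlock_total,
                existing.all_strands,
            )
        else:
            rc = _parse_class(spec, rid)
            face = spec.get("face")
            group = spec.get("group")
            if face is None or group is None:
                raise RuleConfigError(f"new rule {rid!r}: needs 'face' and 'group'")
            per_strand = {}
            il = nil = allb = None
        face_map = {
            "hydrophobic": FACE_HYDROPHOBIC,
            "hydrophilic": FACE_HYDROPHILIC,
            "any": FACE_ANY,
        }
        face = face_map.get(face, face)
        if "per_strand" in spec:
            if spec["per_strand"] is None:
                per_strand = {}
            else:
                for k, v in dict(spec["per_strand"]).items():
                    k = int(k)
                    if not 1 <= k <= 7:
                        raise RuleConfigError(
                            f"rule {rid!r}: strand index {k} outside 1..7"
                        )
                    b = _parse_bound(v, f"rule {rid!r} strand {k}")
                    if b is None:
                        per_strand.pop(k, None)
                    else:
                        per_strand[k] = b
        if "interlock" in spec:
            il = _parse_bound(spec["interlock"], f"rule {rid!r} interlock")
        if "non_interlock" in spec:
            nil = _parse_bound(spec["non_interlock"], f"rule {rid!r} non_interlock")
        if "all" in spec:
            allb = _parse_bound(spec["all"], f"rule {rid!r} all")
        new = Rule(
            id=rid,
            group=group,
            descriptor=CountDescriptor(rc, face),
            per_strand=per_strand,
            interlock_total=il,
            non_interlock_total=nil,
            all_strands=allb,
            provenance="user",
        )
        if existing is not None:
            rules = [new if r.id == rid else r for r in rules]
        else:
            rules.append(new)

    return RuleSet(
        geometry=geometry,
        strand_rules=tuple(rules),
        loop_rules=loop_rules,
        name=str(doc.get("name", "user")) if doc else base.name,
    )
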