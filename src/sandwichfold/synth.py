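"""Labeled synthetic sequences: guaranteed positives, targeted negatives,
random background.

Positives are built constructively from a verified template rather than by
rejection-sampling raw random strings (the acceptance probability of a
random string is astronomically small).  Each template position carries a
menu of substitutions chosen so that every residue-class count the grammar
inspects is unchanged (or provably stays within bounds); the result is then
re-verified with :func:`~sandwichfold.model.check_assignment`.

Targeted negatives are engineered so that *no* placement can satisfy the
chosen rule group, and that is verified at generation time by exhaustive
enumeration under the group-only rule set.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import SandwichfoldError
from .model import Assignment, RuleSet, check_assignment, default_ruleset
from .residues import AMINO_ACIDS
from .search import ORACLE_LENGTH_GUARD, enumerate_satisfying, search

logger = logging.getLogger(__name__)

NEGATIVE_GROUPS = ("GEOMETRY", "T1", "T2", "T3", "LOOPS")

#: Fixed worked positive: seven strands at 1-based starts 1,12,23,34,45,56,67
#: separated by five-residue glycine loops.  Satisfies every default rule.
WORKED_POSITIVE = (
    "VQVASQ" "GGGGG" "FQVAVQ" "GGGGG" "VQVAVQ" "GGGGG" "VQSQNQ"
    "GGGGG" "VQAQVK" "GGGGG" "VQCQVY" "GGGGG" "VQSQTE"
)

WORKED_POSITIVE_ASSIGNMENT = Assignment((0, 11, 22, 33, 44, 55, 66), 72)

# Substitution menus per strand position.  Within a menu every letter has
# identical membership across all residue classes the rules count, except
# where noted; class counts therefore match the verified template.
#   V<->I/L/M  (strong aliphatic hydrophobics)
#   F<->W      (strong aromatic hydrophobics)
#   Q<->S/T    (uncharged hydrophilics)
#   K<->R/H    (charged, non-disruptor)
#   E<->D      (charged disruptors)
#   strand-5 core Ala may become Cys (both stay within their count caps)
_STRAND_MENUS: tuple[tuple[str, ...], ...] = (
    ("VILM", "QST", "VILM", "A", "QST", "QST"),   # strand 1
    ("FW", "QST", "VILM", "A", "VILM", "QST"),    # strand 2
    ("VILM", "QST", "VILM", "A", "VILM", "QST"),  # strand 3
    ("VILM", "QST", "QST", "QST", "N", "QST"),    # strand 4
    ("VILM", "QST", "AC", "QST", "VILM", "KRH"),  # strand 5
    ("VILM", "QST", "C", "QST", "VILM", "Y"),     # strand 6
    ("VILM", "QST", "QST", "QST", "QST", "ED"),   # strand 7
)

_LOOP_MENU = "GP"
_TAIL_MENU = "QSTNDE"


@dataclass(frozen=True)
class AnnotatedSequence:
    """A test-fixture sequence with its ground truth."""

    id: str
    sequence: str
    label: str  # "positive" | "negative" | "random"
    true_assignment: Optional[Assignment] = None
    violated_group: Optional[str] = None
    seed: Optional[int] = None


@dataclass(frozen=True)
class PositiveParams:
    loop_lengths: tuple[int, ...] = (5, 5, 5, 5, 5, 5)
    n_tail: int = 0
    c_tail: int = 0

    def __post_init__(self) -> None:
        if len(self.loop_lengths) != 6:
            raise SandwichfoldError("exactly six loop lengths are required")
        if self.n_tail < 0 or self.c_tail < 0:
            raise SandwichfoldError("tail lengths must be >= 0")


def _build_positive(rng: random.Random, params: PositiveParams) -> tuple[str, Assignment]:
    strands = [
        "".join(rng.choice(menu) for menu in strand_menu)
        for strand_menu in _STRAND_MENUS
    ]
    loops = [
        "".join(rng.choice(_LOOP_MENU) for _ in range(n))
        for n in params.loop_lengths
    ]
    n_tail = "".join(rng.choice(_TAIL_MENU) for _ in range(params.n_tail))
    c_tail = "".join(rng.choice(_TAIL_MENU) for _ in range(params.c_tail))
    parts = [n_tail]
    starts = []
    pos = len(n_tail)
    for i, strand in enumerate(strands):
        starts.append(pos)
        parts.append(strand)
        pos += len(strand)
        if i < 6:
            parts.append(loops[i])
            pos += len(loops[i])
    parts.append(c_tail)
    seq = "".join(parts)
    return seq, Assignment(tuple(starts), len(seq))


def generate_positive(params: Optional[PositiveParams] = None,
                      seed: int = 0,
                      ruleset: Optional[RuleSet] = None,
                      id: str = "pos") -> AnnotatedSequence:
    """A sequence guaranteed to satisfy the full rule set, with known strands."""
    params = params or PositiveParams()
    rs = ruleset or default_ruleset()
    rng = random.Random(seed)
    for attempt in range(50):
        seq, assignment = _build_positive(rng, params)
        report = check_assignment(seq, assignment, rs)
        if report.satisfied:
            return AnnotatedSequence(
                id=id, sequence=seq, label="positive",
                true_assignment=assignment, seed=seed,
            )
        logger.debug("positive attempt %d violated %s", attempt, report.rule_ids())
    raise SandwichfoldError(
        "could not generate a satisfying positive; the requested parameters "
        "(loop lengths, rule overrides) may be unsatisfiable"
    )


@dataclass(frozen=True)
class NegativeParams:
    length: int = 90


def _force_period(seq: list[str], letter: str, period: int = 3) -> None:
    for i in range(0, len(seq), period):
        seq[i] = letter


def generate_negative(violated_group: str,
                      params: Optional[NegativeParams] = None,
                      seed: int = 0,
                      ruleset: Optional[RuleSet] = None,
                      id: str = "neg") -> AnnotatedSequence:
    """A sequence no placement can reconcile with the chosen rule group.

    GEOMETRY: shorter than the minimum span.  T1: Gly at every third
    position, so every window has Gly at a core-facing position.  T2: no
    hydrophilic residues at all.  T3: Pro at every third position, blowing
    the whole-strand Pro budget for any seven windows.  LOOPS: no
    favorable-in-loops residues anywhere, so no fragment can score as a
    loop.  Unsatisfiability under the group-only rule set is verified by
    exhaustive enumeration.
    """
    if violated_group not in NEGATIVE_GROUPS:
        raise SandwichfoldError(
            f"unknown negative group {violated_group!r}; "
            f"choose from {NEGATIVE_GROUPS}"
        )
    params = params or NegativeParams()
    rs = ruleset or default_ruleset()
    rng = random.Random(seed)
    if violated_group == "GEOMETRY":
        length = min(params.length, rs.geometry.min_span() - 12)
        seq = "".join(rng.choice(sorted(AMINO_ACIDS)) for _ in range(length))
        check_rs = rs
    elif violated_group == "T1":
        chars = [rng.choice("VQSTALIEK") for _ in range(params.length)]
        _force_period(chars, "G")
        seq = "".join(chars)
        check_rs = rs.subset({"T1"})
    elif violated_group == "T2":
        seq = "".join(rng.choice("VILMFAWC") for _ in range(params.length))
        check_rs = rs.subset({"T2"})
    elif violated_group == "T3":
        chars = [rng.choice("VQSTALIEK") for _ in range(params.length)]
        _force_period(chars, "P")
        seq = "".join(chars)
        check_rs = rs.subset({"T3"})
    else:  # LOOPS
        seq = "".join(rng.choice("VQEK") for _ in range(params.length))
        check_rs = rs.subset({"LOOPS"})
    if len(seq) <= ORACLE_LENGTH_GUARD:
        witnesses = enumerate_satisfying(seq, check_rs)
        if witnesses:
            raise SandwichfoldError(
                f"negative construction for group {violated_group} failed "
                f"verification ({len(witnesses)} satisfying assignments)"
            )
    return AnnotatedSequence(
        id=id, sequence=seq, label="negative",
        violated_group=violated_group, seed=seed,
    )


def generate_random(length_range: tuple[int, int] = (72, 120),
                    composition="uniform",
                    seed: int = 0,
                    id: str = "rand") -> AnnotatedSequence:
    """An i.i.d. background sequence (truth unknown, label 'random')."""
    rng = random.Random(seed)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise SandwichfoldError(f"bad length range ({lo},{hi})")
    length = rng.randint(lo, hi)
    if composition == "uniform" or composition is None:
        letters = sorted(AMINO_ACIDS)
        weights = [1.0] * len(letters)
    else:
        comp = dict(composition)
        bad = set(comp) - AMINO_ACIDS
        if bad:
            raise SandwichfoldError(f"unknown residues in composition: {sorted(bad)}")
        if any(v < 0 for v in comp.values()):
            raise SandwichfoldError("negative residue frequency")
        total = float(sum(comp.values()))
        if total <= 0:
            raise SandwichfoldError("residue frequencies sum to zero")
        if abs(total - 1.0) > 1e-9:
            logger.warning(
                "residue frequencies sum to %.6g; renormalizing", total
            )
        letters = sorted(comp)
        weights = [comp[c] / total for c in letters]
    seq = "".join(rng.choices(letters, weights=weights, k=length))
    return AnnotatedSequence(id=id, sequence=seq, label="random", seed=seed)


def positive_biased_composition(seed: int = 0, n_templates: int = 10) -> dict[str, float]:
    """Letter frequencies of generated positives (for hard background sets)."""
    counts: dict[str, int] = {}
    for i in range(n_templates):
        pos = generate_positive(seed=seed * 10007 + i)
        for c in pos.sequence:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    return {c: n / total for c, n in sorted(counts.items())}


def make_benchmark(n_pos: int, n_neg_per_group: int, n_random: int,
                   seed: int = 0,
                   random_length_range: tuple[int, int] = (72, 120),
                   random_composition="uniform") -> list[AnnotatedSequence]:
    """A deterministic shuffled mix of positives, targeted negatives and
    random background sequences."""
    if min(n_pos, n_neg_per_group, n_random) < 0:
        raise SandwichfoldError("benchmark counts must be >= 0")
    rng = random.Random(seed)
    records: list[AnnotatedSequence] = []
    for i in range(n_pos):
        lens = tuple(rng.randint(5, 10) for _ in range(6))
        records.append(
            generate_positive(
                PositiveParams(loop_lengths=lens),
                seed=seed * 1_000_003 + i,
                id=f"pos{i + 1:04d}",
            )
        )
    for group in NEGATIVE_GROUPS:
        for i in range(n_neg_per_group):
            records.append(
                generate_negative(
                    group,
                    seed=seed * 1_000_033 + i,
                    id=f"neg_{group.lower()}{i + 1:04d}",
                )
            )
    for i in range(n_random):
        records.append(
            generate_random(
                random_length_range,
                random_composition,
                seed=seed * 1_000_037 + i,
                id=f"rand{i + 1:04d}",
            )
        )
    rng.shuffle(records)
    return records


def verify_soundness(records: Sequence[AnnotatedSequence],
                     ruleset: Optional[RuleSet] = None) -> None:
    """Assert the generator contracts: positives accepted, negatives rejected."""
    rs = ruleset or default_ruleset()
    for rec in records:
        if rec.label == "random":
            continue
        decision = search(rec.sequence, rs)
        if rec.label == "positive" and not decision.accepted:
            raise SandwichfoldError(f"generated positive {rec.id} rejected")
        if rec.label == "negative" and decision.accepted:
            raise SandwichfoldError(f"generated negative {rec.id} accepted")
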