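"""Sensitivity/specificity scoring, rule-group ablation, bound fitting.

The ablation presets mirror the published sensitivity/specificity design:
run the classifier with only some rule groups active (or with the strand-2/3
core-hydrophobic requirement relaxed) and compare acceptance counts.  The
absolute published counts are not reproducible without the external
structure-database sequence sets; see ``scripts/astral_ablation_stub.py``
for how to run the presets against user-supplied data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .errors import SandwichfoldError
from .model import (
    Bound,
    Rule,
    RuleSet,
    count_feature,
    default_ruleset,
)
from .search import Decision, SearchParams, search
from .synth import AnnotatedSequence


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts and rates for one classifier run over a labeled set."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0
    per_group: dict = field(default_factory=dict)  # group -> (accepted, total)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_accepted(self) -> int:
        return self.tp + self.fp

    @property
    def sensitivity(self) -> Optional[float]:
        pos = self.tp + self.fn
        return None if pos == 0 else self.tp / pos

    @property
    def specificity(self) -> Optional[float]:
        neg = self.tn + self.fp
        return None if neg == 0 else self.tn / neg

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity": (
                None if self.sensitivity is None else round(self.sensitivity, 3)
            ),
            "specificity": (
                None if self.specificity is None else round(self.specificity, 3)
            ),
            "per_group": dict(self.per_group),
        }


def evaluate(records: Sequence[AnnotatedSequence], ruleset: RuleSet,
             params: Optional[SearchParams] = None,
             decisions: Optional[dict[str, Decision]] = None) -> ConfusionSummary:
    """Classify a labeled set and summarize the confusion counts.

    Every record must carry a ``positive`` or ``negative`` label; records
    labeled ``random`` must be relabeled by the caller first.  If
    ``decisions`` is given, it is used as a cache keyed by record id.
    """
    params = params or SearchParams()
    tp = fn = fp = tn = 0
    per_group: dict[str, list[int]] = {}
    for rec in records:
        if rec.label not in ("positive", "negative"):
            raise SandwichfoldError(
                f"record {rec.id!r} has label {rec.label!r}; evaluation needs "
                "'positive' or 'negative'"
            )
        if decisions is not None and rec.id in decisions:
            decision = decisions[rec.id]
        else:
            decision = search(rec.sequence, ruleset, params)
            if decisions is not None:
                decisions[rec.id] = decision
        accepted = decision.accepted
        if rec.label == "positive":
            tp += accepted
            fn += not accepted
        else:
            fp += accepted
            tn += not accepted
            group = rec.violated_group or "unlabeled"
            acc, tot = per_group.get(group, (0, 0))
            per_group[group] = (acc + int(accepted), tot + 1)
    return ConfusionSummary(tp=tp, fn=fn, fp=fp, tn=tn,
                            per_group=dict(per_group))


# ---------------------------------------------------------------------------
# ablation presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationPreset:
    name: str
    groups: tuple[str, ...]
    ruleset: RuleSet
    note: str = ""


def relax_interlock_core(ruleset: RuleSet) -> RuleSet:
    """Cap core-facing hydrophobics in strands 2 and 3 at two instead of
    requiring exactly three; the interlock total stays at >= 9."""
    r = ruleset.get_rule("t1r1")
    per_strand = dict(r.per_strand)
    per_strand[2] = Bound(0, 2)
    per_strand[3] = Bound(0, 2)
    return ruleset.with_rule(
        replace(r, per_strand=per_strand), name="all+s23cap2"
    )


def ablation_presets(base: Optional[RuleSet] = None) -> list[AblationPreset]:
    """The six rule-subset configurations of the ablation experiment."""
    rs = base or default_ruleset()
    return [
        AblationPreset("all", ("T1", "T2", "T3", "LOOPS"), rs,
                       "complete rule set"),
        AblationPreset("T3", ("T3",), rs.subset({"T3"}),
                       "whole-strand rules only"),
        AblationPreset("T2+T3", ("T2", "T3"), rs.subset({"T2", "T3"}),
                       "surface-position + whole-strand rules"),
        AblationPreset("T1+T3", ("T1", "T3"), rs.subset({"T1", "T3"}),
                       "core-position + whole-strand rules"),
        AblationPreset("T1", ("T1",), rs.subset({"T1"}),
                       "core-position rules only"),
        AblationPreset("all+s23cap2", ("T1", "T2", "T3", "LOOPS"),
                       relax_interlock_core(rs),
                       "complete set, strands 2/3 core hydrophobics <= 2"),
    ]


def run_ablation(records: Sequence[AnnotatedSequence],
                 presets: Optional[Sequence[AblationPreset]] = None,
                 params: Optional[SearchParams] = None) -> pd.DataFrame:
    """Evaluate every preset on the same labeled set.

    Returns one row per preset with raw counts, rates (3 decimals) and the
    accepted-set size (for nestedness checks).
    """
    presets = presets if presets is not None else ablation_presets()
    rows = []
    for preset in presets:
        summary = evaluate(records, preset.ruleset, params)
        rows.append(
            {
                "preset": preset.name,
                "groups": "+".join(preset.groups),
                "tp": summary.tp,
                "fn": summary.fn,
                "fp": summary.fp,
                "tn": summary.tn,
                "n_accepted": summary.n_accepted,
                "sensitivity": (
                    None if summary.sensitivity is None
                    else round(summary.sensitivity, 3)
                ),
                "specificity": (
                    None if summary.specificity is None
                    else round(summary.specificity, 3)
                ),
            }
        )
    return pd.DataFrame(rows)


def accepted_ids(records: Sequence[AnnotatedSequence], ruleset: RuleSet,
                 params: Optional[SearchParams] = None) -> set[str]:
    """Ids of the records the rule set accepts (helper for nestedness)."""
    params = params or SearchParams()
    return {
        rec.id for rec in records
        if search(rec.sequence, ruleset, params).accepted
    }


# ---------------------------------------------------------------------------
# bound fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Observed count ranges per rule/scope plus the induced rule set."""

    observed: dict  # rule id -> {scope: (min, max)}
    ruleset: RuleSet


def fit_bounds(records: Sequence[AnnotatedSequence],
               ruleset: Optional[RuleSet] = None) -> FitResult:
    """Empirical [min, max] count intervals over annotated positives.

    Every record must carry its true assignment.  For each rule descriptor
    and scope the observed minimum and maximum counts over the set become
    the bounds of a candidate rule set.
    """
    rs = ruleset or default_ruleset()
    records = [r for r in records]
    if not records:
        raise SandwichfoldError("fit_bounds needs at least one record")
    for rec in records:
        if rec.true_assignment is None:
            raise SandwichfoldError(
                f"record {rec.id!r} has no true assignment; fit_bounds needs "
                "explicit strand coordinates"
            )
    observed: dict[str, dict[str, tuple[int, int]]] = {}
    fitted_rules: list[Rule] = []
    for rule in rs.strand_rules:
        scopes: dict[str, tuple[int, int]] = {}
        for rec in records:
            counts = count_feature(
                rec.sequence, rec.true_assignment, rule.descriptor, rs.geometry
            )
            values = {
                **{f"strand_{k}": counts.per_strand[k - 1] for k in range(1, 8)},
                "interlock": counts.interlock_total,
                "non_interlock": counts.non_interlock_total,
                "all": counts.all_total,
            }
            for scope, v in values.items():
                if scope in scopes:
                    mn, mx = scopes[scope]
                    scopes[scope] = (min(mn, v), max(mx, v))
                else:
                    scopes[scope] = (v, v)
        observed[rule.id] = scopes
        fitted_rules.append(
            replace(
                rule,
                per_strand={
                    k: Bound(*scopes[f"strand_{k}"]) for k in range(1, 8)
                },
                interlock_total=Bound(*scopes["interlock"]),
                non_interlock_total=Bound(*scopes["non_interlock"]),
                all_strands=Bound(*scopes["all"]),
                provenance=f"fitted from {len(records)} annotated sequences",
            )
        )
    fitted = RuleSet(
        geometry=rs.geometry,
        strand_rules=tuple(fitted_rules),
        loop_rules=rs.loop_rules,
        name="fitted",
    )
    return FitResult(observed=observed, ruleset=fitted)
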