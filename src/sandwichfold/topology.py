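"""Abstract supersecondary-structure analysis for two-sheet sandwiches.

A topology is a purely combinatorial object: sequence-numbered strands,
their spatial order within each beta sheet, and the set of H-bonded
neighbor pairs.  No 3D coordinates are involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .errors import TopologyError


@dataclass(frozen=True)
class SSSTopology:
    """Strand arrangement: sheets (spatial order) and H-bonded pairs."""

    n_strands: int
    sheets: tuple[tuple[int, ...], ...]
    hbond_pairs: frozenset[frozenset[int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sheets", tuple(tuple(s) for s in self.sheets))
        object.__setattr__(
            self, "hbond_pairs", frozenset(frozenset(p) for p in self.hbond_pairs)
        )

    def validate(self) -> None:
        all_strands = [s for sheet in self.sheets for s in sheet]
        expected = list(range(1, self.n_strands + 1))
        if sorted(all_strands) != expected:
            raise TopologyError(
                f"sheets must contain each strand 1..{self.n_strands} exactly once, "
                f"got {sorted(all_strands)}"
            )
        if any(not sheet for sheet in self.sheets):
            raise TopologyError("empty sheet")
        adjacent = sheet_adjacency(self.sheets)
        for pair in self.hbond_pairs:
            if len(pair) != 2:
                raise TopologyError(f"hbond pair {sorted(pair)} is not a pair")
            if pair not in adjacent:
                raise TopologyError(
                    f"hbond pair {sorted(pair)} is not adjacent within any sheet"
                )

    @classmethod
    def from_dict(cls, doc: dict) -> "SSSTopology":
        try:
            topo = cls(
                n_strands=int(doc["n_strands"]),
                sheets=tuple(tuple(int(s) for s in sheet) for sheet in doc["sheets"]),
                hbond_pairs=frozenset(
                    frozenset(int(s) for s in pair) for pair in doc["hbond_pairs"]
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise TopologyError(f"malformed topology document: {exc}") from exc
        topo.validate()
        return topo

    @classmethod
    def from_json(cls, path) -> "SSSTopology":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "n_strands": self.n_strands,
            "sheets": [list(s) for s in self.sheets],
            "hbond_pairs": sorted(sorted(p) for p in self.hbond_pairs),
        }


@dataclass(frozen=True)
class Strandon:
    """Maximal run of consecutive strands that are pairwise H-bonded."""

    members: tuple[int, ...]


@dataclass(frozen=True)
class Interlock:
    """Cross-sheet pairing (i,j) / (i+1,j+1) of two consecutive-strand pairs."""

    i: int
    i1: int
    j: int
    j1: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.i, self.i1, self.j, self.j1)


@dataclass(frozen=True)
class ConstraintViolation:
    constraint: str  # "C1" | "C2" | "C2-not-applicable"
    strands: tuple[int, ...]
    detail: str


def sheet_adjacency(sheets: Sequence[Sequence[int]]) -> dict[frozenset[int], int]:
    """Map each spatially adjacent pair to the index of its sheet."""
    adj: dict[frozenset[int], int] = {}
    for idx, sheet in enumerate(sheets):
        for a, b in zip(sheet, sheet[1:]):
            adj[frozenset((a, b))] = idx
    return adj


def partition_strandons(topology: SSSTopology) -> list[Strandon]:
    """Split strands 1..n into strandons, ordered by first member.

    Two consecutive strands belong to the same strandon iff they share
    H-bonds; a strand with no H-bonded sequence neighbor is a singleton.
    """
    topology.validate()
    runs: list[list[int]] = []
    current = [1]
    for s in range(2, topology.n_strands + 1):
        if frozenset((s - 1, s)) in topology.hbond_pairs:
            current.append(s)
        else:
            runs.append(current)
            current = [s]
    runs.append(current)
    return [Strandon(tuple(r)) for r in runs]


def check_arrangement_constraints(topology: SSSTopology) -> list[ConstraintViolation]:
    """Check the two arrangement constraints; empty list means both hold.

    C1: sequence-consecutive strands that are not H-bonded may not share a
    sheet.  C2: some cyclically consecutive strand pair sits at the left
    edges of the two sheets, and some pair at the right edges.  With a
    number of sheets other than two, C2 is reported as not applicable
    rather than raising.
    """
    topology.validate()
    out: list[ConstraintViolation] = []
    sheet_of = {
        s: idx for idx, sheet in enumerate(topology.sheets) for s in sheet
    }
    for s in range(1, topology.n_strands):
        pair = frozenset((s, s + 1))
        if pair not in topology.hbond_pairs and sheet_of[s] == sheet_of[s + 1]:
            out.append(
                ConstraintViolation(
                    "C1",
                    (s, s + 1),
                    f"consecutive strands {s} and {s + 1} share sheet "
                    f"{sheet_of[s]} without H-bonds",
                )
            )
    if len(topology.sheets) != 2:
        out.append(
            ConstraintViolation(
                "C2-not-applicable",
                (),
                f"edge constraint needs exactly 2 sheets, topology has "
                f"{len(topology.sheets)}",
            )
        )
        return out
    n = topology.n_strands

    def cyclic_consecutive(a: int, b: int) -> bool:
        return abs(a - b) == 1 or (n > 1 and {a, b} == {1, n})

    a_sheet, b_sheet = topology.sheets
    for side, ea, eb in (("left", a_sheet[0], b_sheet[0]),
                         ("right", a_sheet[-1], b_sheet[-1])):
        if not cyclic_consecutive(ea, eb):
            out.append(
                ConstraintViolation(
                    "C2",
                    (ea, eb),
                    f"{side}-edge strands {ea} and {eb} are not consecutive",
                )
            )
    return out


def find_interlocks(topology: SSSTopology) -> list[Interlock]:
    """All quadruples (i, i+1, j, j+1) pairing across the two sheets.

    Requires exactly two sheets.  (i, j) must be spatial neighbors in one
    sheet and (i+1, j+1) in the other, with i+1 < j.  Results are sorted by
    ascending i, then j.
    """
    topology.validate()
    if len(topology.sheets) != 2:
        raise TopologyError(
            f"interlock analysis needs exactly 2 sheets, got {len(topology.sheets)}"
        )
    adj = sheet_adjacency(topology.sheets)
    n = topology.n_strands
    out: list[Interlock] = []
    for i in range(1, n):
        for j in range(i + 2, n):
            s1 = adj.get(frozenset((i, j)))
            s2 = adj.get(frozenset((i + 1, j + 1)))
            if s1 is not None and s2 is not None and s1 != s2:
                out.append(Interlock(i, i + 1, j, j + 1))
    return out


def is_sandwich_invariant(topology: SSSTopology) -> bool:
    """True iff the topology contains at least one interlock."""
    return bool(find_interlocks(topology))


def fig_sandwich_topology() -> SSSTopology:
    """The canonical seven-strand sandwich arrangement used in examples."""
    return SSSTopology(
        n_strands=7,
        sheets=((1, 2, 5, 4), (7, 6, 3)),
        hbond_pairs=frozenset(
            frozenset(p) for p in ((1, 2), (2, 5), (5, 4), (7, 6), (6, 3))
        ),
    )
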