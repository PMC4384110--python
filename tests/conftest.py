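import random

import pytest

from sandwichfold import (
    WORKED_POSITIVE,
    WORKED_POSITIVE_ASSIGNMENT,
    check_assignment,
    default_ruleset,
    enumerate_candidate_assignments,
)
from sandwichfold.topology import SSSTopology, fig_sandwich_topology


@pytest.fixture(scope="session")
def rs():
    return default_ruleset()


@pytest.fixture(scope="session")
def worked_seq():
    return WORKED_POSITIVE


@pytest.fixture(scope="session")
def worked_assignment():
    return WORKED_POSITIVE_ASSIGNMENT


@pytest.fixture(scope="session")
def fig1_topology():
    return fig_sandwich_topology()


def flat_oracle(sequence, ruleset):
    """Independent route: structural enumeration + pure per-candidate check.

    Shares no pruning logic with the backtracking engine.
    """
    return [
        a
        for a in enumerate_candidate_assignments(len(sequence), ruleset.geometry)
        if check_assignment(sequence, a, ruleset).satisfied
    ]


def random_two_sheet_topology(rng: random.Random, n: int) -> SSSTopology:
    """A random valid topology: strands split over two sheets, H-bonds a
    random subset of the within-sheet adjacencies."""
    strands = list(range(1, n + 1))
    rng.shuffle(strands)
    cut = rng.randint(1, n - 1)
    sheets = (tuple(strands[:cut]), tuple(strands[cut:]))
    adjacent = [
        frozenset((a, b)) for sheet in sheets for a, b in zip(sheet, sheet[1:])
    ]
    hbonds = frozenset(p for p in adjacent if rng.random() < 0.7)
    return SSSTopology(n_strands=n, sheets=sheets, hbond_pairs=hbonds)
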