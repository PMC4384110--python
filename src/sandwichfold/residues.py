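"""Amino-acid alphabet, residue classes and loop weights.

All classes are sets of one-letter codes over the standard 20 amino acids.
The class definitions are the vocabulary of the count-constraint rules; the
rules themselves live in :mod:`sandwichfold.model`.
"""

from __future__ import annotations

AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Letters tolerated on input but belonging to no class.
AMBIGUOUS_LETTERS: frozenset[str] = frozenset("XBZUJO*")

CLASSES: dict[str, frozenset[str]] = {
    "HYDROPHOBIC": frozenset("WIFLCVMAY"),
    "STRONG_HYDROPHOBIC": frozenset("WIFLVM"),
    "AROMATIC": frozenset("FWY"),
    "CHARGED": frozenset("DERKH"),
    "HYDROPHILIC": frozenset("QERTSYDHKN"),
    "ALA": frozenset("A"),
    "CYS": frozenset("C"),
    "TYR": frozenset("Y"),
    "PRO": frozenset("P"),
    "GLY": frozenset("G"),
    "PRO_GLY": frozenset("PG"),
    "PRO_GLY_ALA": frozenset("PGA"),
    "DISRUPTOR5": frozenset("PGNDE"),
}

#: Integer weights of the loop-favorable function.  Gly/Pro score 2, the
#: milder turn-formers score 1, everything else 0.
LOOP_WEIGHTS: dict[str, int] = {
    "G": 2,
    "P": 2,
    "D": 1,
    "N": 1,
    "H": 1,
    "S": 1,
    "T": 1,
}


def class_members(name: str) -> frozenset[str]:
    """Return the member set of a built-in residue class."""
    try:
        return CLASSES[name]
    except KeyError:
        raise KeyError(f"unknown residue class {name!r}") from None
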