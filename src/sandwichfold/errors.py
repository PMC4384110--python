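"""Exception hierarchy shared across the package."""


class SandwichfoldError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(SandwichfoldError):
    """Invalid supersecondary-structure description."""


class RuleConfigError(SandwichfoldError):
    """Malformed rule-set definition or override document."""


class AssignmentError(SandwichfoldError):
    """Strand/loop assignment inconsistent with the geometry or sequence."""


class SequenceError(SandwichfoldError):
    """Bad input sequence (empty, non-standard letters in strict mode, ...)."""


class DataError(SandwichfoldError):
    """Malformed data file (FASTA, truth table, topology JSON)."""
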