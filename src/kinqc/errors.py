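"""Exception hierarchy shared across the package."""


class KinqcError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KinqcError):
    """Malformed textual input (tabular row or CLIF text).

    Carries enough position information (row number or character offset)
    to locate the offending construct.
    """

    def __init__(self, message: str, *, row: int | None = None, pos: int | None = None):
        self.row = row
        self.pos = pos
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if pos is not None:
            loc.append(f"offset {pos}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


class MissingPersonError(KinqcError):
    """A link, bond, quality or query references an unregistered person id."""


class TimeScaleError(KinqcError):
    """Calendar dates and integer ticks were compared or mixed in one fact base."""


class InconsistentFactBaseError(KinqcError):
    """The parent-link graph contains a cycle; ancestry is undefined."""


class GenerationError(KinqcError):
    """Synthetic-pedigree or ontology-bundle generation received infeasible input."""


class UnsupportedFragmentError(KinqcError):
    """An axiom falls outside the Horn fragment the rule engine accepts."""


class SafetyError(KinqcError):
    """A rule's consequent uses a variable that never occurs in its antecedent."""
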