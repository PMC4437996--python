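"""Exception hierarchy shared by all rqlnet modules."""


class RqlnetError(Exception):
    """Base class for all rqlnet errors."""


class FormatError(RqlnetError):
    """Malformed tabular input (ragged rows, duplicate names, missing id column)."""


class DegenerateAttributeError(RqlnetError):
    """An operation requiring spread was applied to a constant attribute."""

    def __init__(self, attribute: str):
        self.attribute = attribute
        super().__init__(f"attribute {attribute!r} has zero spread")


class ParseError(RqlnetError):
    """Syntax error in a FINDRULES statement, with 1-based position."""

    def __init__(self, message: str, line: int, column: int):
        self.line = line
        self.column = column
        super().__init__(f"{message} (line {line}, column {column})")


class BindingError(RqlnetError):
    """A query references a dataset, attribute or tuple variable that does not resolve."""


class EvaluationError(RqlnetError):
    """A predicate could not be evaluated on a unit (e.g. arithmetic on a label)."""


class UndefinedMeasureError(RqlnetError):
    """An interest measure is undefined (zero antecedent or consequent count)."""


class InsufficientDegreesError(RqlnetError):
    """Scale-free regression needs at least three distinct positive degrees."""


class GenerationError(RqlnetError):
    """A synthetic-data request is internally inconsistent."""
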