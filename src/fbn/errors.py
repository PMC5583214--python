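"""Exception hierarchy for the fbn package."""


class FbnError(Exception):
    """Base class for all fbn-specific errors."""


class FormatError(FbnError, ValueError):
    """A file's structure is wrong (ragged rows, missing columns, empty)."""


class ParseError(FbnError, ValueError):
    """A cell could not be parsed; the message names the row/column."""


class DimensionError(FbnError, ValueError):
    """An array has the wrong shape for the requested operation."""


class ParameterError(FbnError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class ContractError(FbnError, ValueError):
    """An input violates a documented precondition (e.g. not standardized)."""


class DegenerateColumnError(FbnError, ValueError):
    """A constant ROI column has zero norm after centering."""
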