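"""Exception types shared across the pipeline stages."""


class HistobofError(Exception):
    """Base class for all histobof errors."""


class ParameterError(HistobofError, ValueError):
    """An argument is outside its legal domain (bad K, empty grid, ...)."""


class DegenerateInputError(HistobofError, ValueError):
    """The input is structurally too small or rank-deficient for the operation."""


class DataError(HistobofError, ValueError):
    """Input data violate a contract (non-finite values, misaligned tables)."""


class EmptyTissueError(HistobofError, ValueError):
    """No admissible tissue window exists in the image."""
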