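"""Exception hierarchy for ruvcoexp."""


class RuvCoexpError(Exception):
    """Base class for all ruvcoexp errors."""


class InvalidInputError(RuvCoexpError):
    """Malformed or inconsistent input data."""


class InvalidParameterError(RuvCoexpError):
    """A parameter violates its admissible range."""


class DegenerateInputError(RuvCoexpError):
    """Input is structurally valid but numerically degenerate (e.g. all-zero)."""


class NumericalRankError(RuvCoexpError):
    """A linear system is rank deficient; a positive ridge penalty is advised."""


class UndefinedMetricError(RuvCoexpError):
    """A metric has an empty denominator (e.g. no truly correlated pairs)."""


class GeneSetMismatchError(RuvCoexpError):
    """Two correlation sets do not cover the same genes."""
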