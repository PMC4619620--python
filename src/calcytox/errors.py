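"""Exception hierarchy for calcytox.

The CLI maps these onto exit codes (configuration errors -> 2, gating
errors -> 3); library users catch them like any ValueError.
"""


class CalcytoxError(Exception):
    """Base class for all calcytox errors."""


class InvalidParameterError(CalcytoxError, ValueError):
    """A parameter value violates its documented domain."""


class ConfigurationError(CalcytoxError, ValueError):
    """A plate/assay configuration is inconsistent or incomplete."""


class GatingError(CalcytoxError, RuntimeError):
    """The live-cell gate cannot be derived (e.g. no usable spontaneous wells)."""
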