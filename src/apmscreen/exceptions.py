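"""Exception hierarchy.

``FormatError`` and ``ValidationError`` signal bad inputs (CLI exit code 1);
``EstimationError`` signals that a quantity could not be estimated from the
data provided (CLI exit code 2), usually with a hint on how to supply it
explicitly.
"""


class ApmscreenError(Exception):
    """Base class for all package errors."""


class FormatError(ApmscreenError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ApmscreenError):
    """Input values violate a documented invariant."""


class EstimationError(ApmscreenError):
    """A data-driven estimate (MST, RIT, cutoff, ...) is undefined."""
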