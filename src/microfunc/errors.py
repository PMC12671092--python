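"""Exception hierarchy.

``MicrofuncError`` is the base for everything the package raises on
purpose; the CLI maps it to exit code 2 (data/validation error), while
usage errors exit with 1.
"""


class MicrofuncError(Exception):
    """Base class for all microfunc errors."""


class ValidationError(MicrofuncError):
    """Malformed or inconsistent input data."""


class PlanError(MicrofuncError):
    """A memory plan cannot be constructed or is inconsistent with the data."""


class InsufficientBudgetError(PlanError):
    """The device byte budget cannot hold even a minimal work unit."""
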