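"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation errors -> 2, estimation
errors -> 3, simulation errors -> 4.
"""


class GLVKitError(Exception):
    """Base class for all glvkit errors."""


class FormatError(GLVKitError):
    """A file does not conform to the expected dialect/layout."""


class ValidationError(GLVKitError):
    """An in-memory object or argument violates an invariant."""


class EstimationError(GLVKitError):
    """Parameter estimation could not proceed."""


class UnderdeterminedSystemError(EstimationError):
    """Too few usable intervals to identify the per-taxon parameters."""


class SimulationError(GLVKitError):
    """Numerical integration failed; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time
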