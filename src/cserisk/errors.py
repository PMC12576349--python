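"""Exception hierarchy for the cserisk pipeline.

Every stage raises a subclass of :class:`CSERiskError` so the CLI can map
failures to a stage name and a nonzero exit code.
"""


class CSERiskError(Exception):
    """Base class for all package errors."""


class ConfigError(CSERiskError, ValueError):
    """Invalid configuration (counts, probabilities, scenario parameters)."""


class InputError(CSERiskError, ValueError):
    """Invalid data input (empty tables, out-of-range values, bad quantile targets)."""


class LinkageError(CSERiskError, KeyError):
    """A household references a block group that does not exist."""


class SeparationError(CSERiskError, RuntimeError):
    """Logistic regression diverged due to complete or quasi-complete separation."""

    def __init__(self, direction: int, message: str | None = None):
        self.direction = direction
        super().__init__(
            message
            or f"complete/quasi-complete separation detected "
            f"(slope diverging {'upward' if direction > 0 else 'downward'})"
        )


class NumericalError(CSERiskError, RuntimeError):
    """A numerical routine (root find, calibration search) failed to converge."""
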