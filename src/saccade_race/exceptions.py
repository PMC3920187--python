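"""Exception hierarchy.

Every error raised by this package derives from :class:`SaccadeRaceError`,
so callers (and the CLI) can report a named error class and exit cleanly.
"""


class SaccadeRaceError(Exception):
    """Base class for all package errors."""


class ParameterError(SaccadeRaceError, ValueError):
    """A model parameter violates its invariants."""


class NumericalInstabilityError(SaccadeRaceError, FloatingPointError):
    """The state became non-finite during integration."""


class InvalidInputError(SaccadeRaceError, ValueError):
    """An analysis operation received unusable input (empty, too short...)."""


class DegenerateDataError(InvalidInputError):
    """Statistically degenerate input (e.g. all paired differences zero)."""


class ConfigError(SaccadeRaceError):
    """Malformed or invalid run configuration."""


class FormatError(SaccadeRaceError):
    """On-disk data does not match the expected schema."""


class CalibrationError(SaccadeRaceError):
    """Kernel calibration failed; carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class FixtureError(SaccadeRaceError):
    """Unknown test-fixture kind."""
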