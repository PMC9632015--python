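"""Exception hierarchy for the TFA macrosimulation model."""


class TFAMMError(Exception):
    """Base class for all package errors."""


class InputError(TFAMMError, ValueError):
    """A caller-supplied value violates a precondition (negative count,
    non-positive denominator, malformed table row, ...)."""


class ConfigError(TFAMMError, ValueError):
    """Inconsistent configuration: mismatched bin grids, scenario rules
    that leave a market channel unmatched, missing table entries."""


class CalibrationError(TFAMMError, RuntimeError):
    """Fixture calibration failed to reproduce its anchor values within
    tolerance."""
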