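"""Exception types shared across the simulator."""


class FearsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FearsimError, ValueError):
    """A network / protocol / run configuration is inconsistent or incomplete."""


class DimensionError(FearsimError, ValueError):
    """Array arguments disagree in shape or length."""


class NumericError(FearsimError, FloatingPointError):
    """NaN or infinity encountered in simulation state."""


class DomainError(FearsimError, ValueError):
    """Scalar argument outside its mathematical domain (e.g. negative time)."""


class CalibrationError(FearsimError, RuntimeError):
    """Home-context baseline calibration failed to converge."""


class ProtocolParseError(FearsimError, ValueError):
    """A stimulus expression does not match the protocol grammar."""
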