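"""Exception types shared across the package."""


class ArbordynError(Exception):
    """Base class for all package-specific errors."""


class SWCFormatError(ArbordynError, ValueError):
    """The SWC file violates the 7-column dialect or the tree invariants."""


class DegenerateFitError(ArbordynError, ValueError):
    """Too few or collinear landmark pairs for a unique rigid fit."""


class DegenerateGeometryError(ArbordynError, ValueError):
    """Point set too degenerate for a 3D hull / alpha complex."""


class UndefinedStatisticError(ArbordynError, ValueError):
    """A statistic has no defined value (e.g. < 2 events for a pair distance)."""


class ScheduleError(ArbordynError, ValueError):
    """Epoch schedule is invalid or does not cover a requested time."""


class InconsistencyError(ArbordynError, ValueError):
    """Branch correspondence table contradicts itself."""


class ConfigError(ArbordynError, ValueError):
    """Run or simulation configuration failed validation."""


class SimulationError(ArbordynError, RuntimeError):
    """The growth simulation reached an unusable state."""
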