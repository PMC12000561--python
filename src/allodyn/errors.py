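"""Exception hierarchy shared across the package."""


class AllodynError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AllodynError):
    """A structured-text input violates its documented schema."""


class IntegrityError(AllodynError):
    """A parsed or constructed object violates a type invariant."""


class FrameError(AllodynError):
    """A trajectory frame is malformed or inconsistent with its topology."""


class SelectionError(AllodynError):
    """A fragment selector matched nothing or could not be parsed."""


class DegeneracyError(AllodynError):
    """Geometry too degenerate for the requested operation."""


class InsufficientDataError(AllodynError):
    """Not enough frames / points for a statistically defined quantity."""


class SingularityError(AllodynError):
    """Overlapping atoms make a pair energy undefined."""


class NodeAssignmentError(AllodynError):
    """A residue cannot be mapped onto network nodes."""


class FitError(AllodynError):
    """A nonlinear fit failed to converge or is undefined."""


class FeasibilityError(AllodynError):
    """A requested synthetic construction is mathematically infeasible."""


class ConfigError(AllodynError):
    """Pipeline configuration is invalid (unknown key, bad value)."""
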