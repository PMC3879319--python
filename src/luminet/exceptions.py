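"""Exception hierarchy for luminet."""


class LuminetError(Exception):
    """Base class for all luminet errors."""


class ConfigError(LuminetError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DataError(LuminetError, ValueError):
    """Invalid data values (non-finite cells, out-of-range scores, ...)."""


class SplitError(LuminetError, ValueError):
    """Invalid or degenerate train/test/validation split."""


class ShapeError(LuminetError, ValueError):
    """Array shape incompatible with a model or operation."""


class PanelError(LuminetError, ValueError):
    """Probe panel too small or focal probe not in the panel."""


class LabelError(LuminetError, ValueError):
    """Class labels unusable (e.g. a class entirely absent)."""


class FixtureLookupError(LuminetError, KeyError):
    """Unknown fixture name; the message lists available fixtures."""


class FormatError(LuminetError, ValueError):
    """Unknown or malformed file format."""


class StatsError(LuminetError, ValueError):
    """Degenerate statistical input (zero margins, single group, no events)."""


class NumericalError(LuminetError, ArithmeticError):
    """Training diverged (NaN loss); the message carries the epoch index."""
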