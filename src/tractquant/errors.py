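"""Exception hierarchy.

Every error raised by tractquant derives from :class:`TractquantError` so
pipeline code can distinguish its own failures from library bugs.
"""


class TractquantError(Exception):
    """Base class for all tractquant errors."""


class ConfigurationError(TractquantError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(TractquantError, ValueError):
    """Input data violate a precondition (wrong group, missing side, ...)."""


class DegenerateFiberError(TractquantError, ValueError):
    """A streamline with zero total arc length cannot be resampled."""


class ExcludedProfileError(TractquantError, ValueError):
    """A profile flagged invalid (discarded tract) was passed downstream."""


class DegenerateVarianceError(TractquantError, ValueError):
    """All within-group variance is zero; the ANOVA F statistic is undefined."""


class IncompleteGridError(TractquantError, KeyError):
    """A taxonomy rule was asked to classify an incomplete comparison grid."""


class SchemaError(TractquantError, ValueError):
    """A table failed schema validation; the message carries row context."""
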