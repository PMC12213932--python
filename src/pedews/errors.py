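"""Exception hierarchy for the pipeline."""


class PedewsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PedewsError):
    """A reference table, variable map or policy file is missing or inconsistent."""


class InvalidReferenceError(PedewsError):
    """A derived reference value is physiologically impossible (e.g. DBP <= 0)."""


class RegistryMismatchError(PedewsError):
    """Feature columns at predict/explain time do not match the fitted registry."""


class UndefinedMetricError(PedewsError):
    """A metric is requested on degenerate input (e.g. single-class labels)."""


class NotFittedError(PedewsError):
    """A transform was applied before being fitted."""
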