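"""Exception types shared across the package."""


class WeakextError(Exception):
    """Base class for all package-specific errors."""


class ParseError(WeakextError):
    """A file could not be parsed (malformed XML, empty input, ...)."""


class SchemaError(WeakextError):
    """A tabular input is missing required columns or has invalid values."""


class DictionaryConflictError(WeakextError):
    """A term dictionary maps the same surface term to two different entities."""


class CommitteeError(WeakextError):
    """The vote set is incomplete or inconsistent (missing/duplicate votes)."""


class NotFittedError(WeakextError):
    """A feature schema or model was used before being fitted/trained."""


class DegenerateTrainingError(WeakextError):
    """Training data contains a single class and no classifier can be fit."""


class ConfigError(WeakextError):
    """An invalid configuration value (e.g. weak-classifier error rate >= 0.5)."""
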