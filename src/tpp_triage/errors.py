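"""Exception hierarchy shared across the package."""


class TppTriageError(Exception):
    """Base class for all package errors."""


class SchemaError(TppTriageError, ValueError):
    """A record is missing a required field or holds an unparseable token."""


class IntegrityError(TppTriageError, ValueError):
    """A collection-level invariant is violated (duplicate ids, drifted fixture)."""


class UsageError(TppTriageError, ValueError):
    """An operation was called on inputs that violate its contract."""


class ConfigError(TppTriageError, ValueError):
    """A configuration object (scheme, generator config) is invalid."""
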