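"""Exception hierarchy shared across the package."""


class KgapError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(KgapError):
    """An input table is malformed: missing columns, unparseable values."""


class IntegrityError(KgapError):
    """Referential integrity or uniqueness violated in the graph."""


class UsageError(KgapError):
    """An operation was called with arguments it cannot work on."""
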