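"""Exception hierarchy shared across the package."""


class IhcmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IhcmarkError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class SchemaError(IhcmarkError, ValueError):
    """An input table is missing required columns or contains invalid rows."""


class GenerationError(IhcmarkError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class ScoringError(IhcmarkError, ValueError):
    """An image yields no scorable content (no tissue, no nuclei, ...)."""


class ProtocolError(IhcmarkError, ValueError):
    """A sample violates the scoring protocol (e.g. fewer than two fields)."""


class InputError(IhcmarkError, ValueError):
    """Degenerate statistical input (empty group, single-class outcome, ...)."""
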