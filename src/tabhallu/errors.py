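"""Shared exception types."""


class TabhalluError(Exception):
    """Base class for package errors."""


class ValidationError(TabhalluError, ValueError):
    """A specification or argument failed validation; message names the field."""


class SchemaError(TabhalluError, ValueError):
    """Two tables disagree on the column set / variable schema."""


class FitError(TabhalluError, RuntimeError):
    """A model fit failed or is unidentifiable."""
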