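"""Exception types shared across the package."""


class LangdxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LangdxError, ValueError):
    """A configuration or function parameter violates its contract."""


class EmptyCorpusError(LangdxError, ValueError):
    """The corpus contains no words at all."""


class DegenerateLabelsError(LangdxError, ValueError):
    """A binary label vector contains only one class."""


class UndefinedAUCError(DegenerateLabelsError):
    """AUC requested for a single-class label vector."""


class InvalidWeightsError(LangdxError, ValueError):
    """Ensemble weights are degenerate (both zero)."""


class SchemaError(LangdxError, ValueError):
    """An input table is missing required columns or has invalid values."""
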