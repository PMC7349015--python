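"""Exception hierarchy shared across the pipeline."""


class CogstatesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CogstatesError):
    """A file does not match its declared schema (column count, dtype...)."""


class MontageMismatchError(FormatError):
    """Channel columns do not match the declared montage."""


class IngestionError(CogstatesError):
    """Content-level problem while reading (NaN cells, bad values)."""


class OrderingError(IngestionError):
    """Event onsets are not strictly increasing."""


class RangeError(IngestionError):
    """A value falls outside its documented range."""


class BaselineError(CogstatesError):
    """Baseline power is non-positive and cannot normalize anything."""


class DegenerateGeometryError(CogstatesError):
    """A landmark denominator collapsed to zero."""


class EmptyWindowError(CogstatesError):
    """A window contains no frames/samples to aggregate."""


class DegenerateTableError(CogstatesError):
    """A contingency table has a zero marginal."""


class UnsupportedModelError(CogstatesError):
    """The fitted model does not expose what was asked of it."""


class ProviderError(CogstatesError):
    """An embedding provider returned inconsistent vectors."""
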