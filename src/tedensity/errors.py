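"""Exception hierarchy shared across the pipeline."""


class TEDensityError(Exception):
    """Base class for all errors raised by this package."""


class AnnotationFormatError(TEDensityError):
    """A required column or field is missing, or a file is unreadable."""


class AnnotationValidationError(TEDensityError):
    """A record violates an invariant (coordinates, strand, uniqueness)."""


class ConsistencyError(TEDensityError):
    """An internal bound was violated, e.g. an overlap sum exceeding its window."""


class StoreError(TEDensityError):
    """A density store is missing, corrupt, or inconsistent."""


class LookupKeyError(TEDensityError):
    """A gene, identity, window, or direction key does not exist."""
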