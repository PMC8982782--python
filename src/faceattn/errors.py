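"""Exception types shared across the package."""


class FaceAttnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FaceAttnError):
    """A file does not conform to the expected CSV layout."""


class ValidationError(FaceAttnError):
    """An in-memory object violates a structural invariant."""


class SchemaError(FaceAttnError):
    """Feature columns or landmark indices do not line up."""


class CoverageError(FaceAttnError):
    """Stimulus events fall outside the recorded session window."""


class InsufficientDataError(FaceAttnError):
    """Not enough usable frames/rows for the requested computation."""


class ClassCoverageError(FaceAttnError):
    """A required class label is absent from the data."""
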