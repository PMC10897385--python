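"""Exception types shared across the package."""


class StcooccurError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StcooccurError, ValueError):
    """A file on disk does not match the expected format (missing sidecar,
    wrong column count, unparsable cell)."""


class ValidationError(StcooccurError, ValueError):
    """An in-memory object violates a data-model invariant (duplicate ids,
    out-of-range probability, negative count)."""
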