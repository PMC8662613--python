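"""Exception hierarchy shared across modules."""


class OgmapperError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OgmapperError):
    """A file on disk does not conform to its documented format."""


class ConsistencyError(OgmapperError):
    """Cross-table referential or structural integrity is violated."""
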