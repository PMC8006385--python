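"""Exception hierarchy shared across the toolkit."""


class OtukitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(OtukitError):
    """An in-memory object violates a structural invariant."""


class ParseError(OtukitError):
    """A file could not be parsed; carries file/line context when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}: "
            if line is not None:
                prefix = f"{path}:{line}: "
        super().__init__(prefix + message)


class VersionError(ParseError):
    """A session archive or BIOM file declares an unsupported format version."""


class CapabilityError(OtukitError):
    """An optional backend (e.g. UMAP) is unavailable in this installation."""


class AnalysisError(OtukitError):
    """A statistical routine received degenerate input (e.g. all-zero sample)."""
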