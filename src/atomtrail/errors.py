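"""Exception hierarchy shared across the package."""


class AtomtrailError(Exception):
    """Base class for all errors raised by atomtrail."""


class MolParseError(AtomtrailError):
    """Malformed MOL/RXN text. Carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MappingIntegrityError(AtomtrailError):
    """An atom-atom map number is not a bijection over the mapped atoms."""


class CapacityError(AtomtrailError):
    """A fixed-width format field or the letter alphabet was exhausted."""


class CanonicalizationError(AtomtrailError):
    """Structure cannot be canonically ordered (e.g. disconnected graph)."""


class ModelFormatError(AtomtrailError):
    """Malformed metabolic-model CSV or ABC text. Carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class StoreError(AtomtrailError):
    """Mapping store cannot be loaded or is internally inconsistent."""


class StoreLookupError(StoreError):
    """Identifier not found in the mapping store."""


class AmbiguousIdentifierError(StoreLookupError):
    """A bare identifier matched more than one stored reaction."""


class BuildError(AtomtrailError):
    """ABC model assembly failed for a reaction."""


class TraceError(AtomtrailError):
    """Label tracing could not follow the requested path."""
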