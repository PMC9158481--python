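"""Exception hierarchy shared across the package."""


class TaxicicleError(Exception):
    """Base class for all package errors."""


class NewickParseError(TaxicicleError):
    """Malformed Newick text; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class TreeValidationError(TaxicicleError):
    """Structurally invalid tree (duplicate leaves, negative lengths, ...)."""


class LineageFormatError(TaxicicleError):
    """A rank-prefixed lineage string violates the seven-rank grammar."""


class TaxonomyFormatError(TaxicicleError):
    """A taxonomy table line is malformed, duplicated, or in the wrong domain."""


class MatchingError(TaxicicleError):
    """Selection/taxonomy matching precondition failure."""


class LayoutError(TaxicicleError):
    """Invalid layout request (bad panel size, unreachable zoom target)."""


class StyleError(TaxicicleError):
    """Invalid palette or out-of-range rank depth."""


class ViewStateError(TaxicicleError):
    """Illegal view-state transition (e.g. hover outside the selection)."""
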