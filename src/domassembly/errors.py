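"""Exception hierarchy.

All package-specific failures derive from :class:`DomainAssemblyError` so a
caller (notably the CLI) can distinguish validation problems from plain I/O
errors, which are left as the builtin ``OSError`` family.
"""


class DomainAssemblyError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DomainAssemblyError, ValueError):
    """Invalid argument values or malformed in-memory objects."""


class GeometryError(ValidationError):
    """Degenerate geometry, e.g. collinear atoms where a frame is needed."""


class LayoutError(ValidationError):
    """Domain layout inconsistent with itself or with a structure."""


class PDBFormatError(DomainAssemblyError):
    """A structure file could not be parsed into any usable residue."""


class InteractionFormatError(DomainAssemblyError):
    """An interaction file is malformed; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateInputError(ValidationError):
    """Structurally valid input that leaves the requested operation empty
    (e.g. no inter-domain pair within the distance cutoff)."""


class GenerationError(DomainAssemblyError):
    """The synthetic generator failed to produce a valid fixture."""
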