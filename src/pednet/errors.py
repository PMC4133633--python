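"""Exception hierarchy shared across the toolkit."""


class PednetError(Exception):
    """Base class for all toolkit errors."""


class PedigreeParseError(PednetError):
    """A pedigree-notation string could not be parsed.

    Carries the character ``offset`` of the offending position when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class PedigreeFormatError(PednetError):
    """A tabular input file violates its format contract."""


class PedigreeStructureError(PednetError):
    """A pedigree net violates a structural invariant (cycle, duplicate)."""


class UnknownLineError(PednetError, KeyError):
    """A named line does not exist in the net or matrix."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message plain
        return Exception.__str__(self)


class GenotypeFormatError(PednetError):
    """A genotype matrix file violates its format contract."""
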