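"""Exception hierarchy for kisse."""


class KisseError(Exception):
    """Base class for all kisse errors."""


class FormatError(KisseError):
    """A peptide table or manifest does not conform to the expected dialect."""


class DuplicatePeptideError(FormatError):
    """The same (peptide, sample) pair appears more than once in a table."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            "duplicated (peptide, sample) pairs: "
            + ", ".join(f"({p!r}, {s!r})" for p, s in self.offenders[:10])
            + ("..." if len(self.offenders) > 10 else "")
        )


class ValidationError(KisseError):
    """Input data violates a model-building requirement."""


class DataError(KisseError):
    """A numeric operation received data it cannot handle."""


class InsufficientDataError(DataError):
    """Not enough observations to carry out a computation."""


class LibraryVersionError(KisseError):
    """Serialized library format version is not supported."""


class LibraryIntegrityError(KisseError):
    """Serialized library is corrupt or truncated."""
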