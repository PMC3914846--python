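"""Exception hierarchy shared across the package."""


class UpepError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(UpepError):
    """An input file violates its declared format."""


class EmptyInputError(UpepError):
    """An input file or collection contains no usable records."""


class NoMorfError(UpepError):
    """No main open reading frame could be located on a transcript."""


class EmptyDatabaseError(UpepError):
    """A uORF database build produced zero usable records."""


class ParameterError(UpepError):
    """A user-supplied parameter violates its contract."""


class InsufficientDataError(UpepError):
    """Too few clean codon columns remain for rate estimation."""


class FixtureSpecError(UpepError):
    """A synthetic-fixture specification is geometrically infeasible."""
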