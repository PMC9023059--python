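"""Exception hierarchy shared by all modules."""


class AltconfError(Exception):
    """Base class for all package errors."""


class ParseError(AltconfError):
    """Malformed input file (A3M/FASTA/PDB); message names the offending record."""


class InputError(AltconfError):
    """Semantically invalid argument (bad interval, alphabet violation, ...)."""


class DomainError(AltconfError):
    """Input outside an operation's mathematical domain (too few points/models)."""


class UndefinedCorrelationError(DomainError):
    """Correlation requested on a profile with zero variance."""
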