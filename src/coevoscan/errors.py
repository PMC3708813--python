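"""Exception hierarchy shared across the package."""


class CoevoscanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CoevoscanError):
    """Input could not be parsed (bad newick, malformed TSV, ...)."""


class ValidationError(CoevoscanError):
    """Input parsed but violates a contract (negative branch length,
    non-binary state, unknown category token, ...)."""


class InsufficientDataError(CoevoscanError):
    """Too few taxa/observations remain to run an analysis."""


class UndefinedScoreError(CoevoscanError):
    """A score (e.g. the client index) is undefined for these inputs."""


class NumericalError(CoevoscanError):
    """A linear solve or optimisation failed beyond recovery."""


class DataMismatchError(CoevoscanError):
    """Two results that must refer to the same data do not."""
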