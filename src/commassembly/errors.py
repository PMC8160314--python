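"""Exception hierarchy for the package.

Validation failures (bad labels, cross-reference mismatches) are kept
distinct from format errors (unparseable files) so the CLI can map them
to different exit codes.
"""


class CommAssemblyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CommAssemblyError):
    """A file could not be parsed into the expected structure."""


class ValidationError(CommAssemblyError):
    """Inputs parsed but violate a contract (labels, cross-references)."""


class UndefinedStatisticError(CommAssemblyError):
    """A statistic is mathematically undefined for the given input."""
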