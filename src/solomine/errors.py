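"""Exception taxonomy.

Exit-code mapping used by the CLI: ConfigError -> 2, data errors
(ParseError, IntegrityError, ValidationError) -> 3, everything else -> 1.
"""


class SoloMineError(Exception):
    """Base class for all package errors."""


class ConfigError(SoloMineError):
    """Invalid configuration (bad keys, mixture not summing to 1, ...)."""


class ParseError(SoloMineError):
    """Malformed input file; message names the file and line where known."""


class IntegrityError(SoloMineError):
    """Cross-file inconsistency (e.g. CDS without a protein sequence)."""


class ValidationError(SoloMineError):
    """Invalid in-memory value (e.g. non-amino-acid characters)."""


class ContractViolationError(SoloMineError):
    """An operation was called outside its stated precondition."""


class DegenerateInputError(SoloMineError):
    """Too little data for the operation to be meaningful (<2 profiles, <3 taxa)."""
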