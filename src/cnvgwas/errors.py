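"""Exception and warning hierarchy shared across the package."""


class CnvGwasError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(CnvGwasError, ValueError):
    """Invalid configuration value (threshold out of range, bad column name...)."""


class FormatError(CnvGwasError, ValueError):
    """A file does not conform to its documented dialect."""


class RowError(FormatError):
    """A single data row is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ResolutionError(FormatError):
    """A marker id or chromosome could not be resolved against the SNP map."""


class ValidationError(CnvGwasError, ValueError):
    """Cross-file consistency or content validation failed."""


class CollinearityError(CnvGwasError, ValueError):
    """The design matrix is singular or numerically rank-deficient."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientDataError(CnvGwasError, ValueError):
    """Fewer complete observations than regression parameters."""


class MonomorphicRegionError(CnvGwasError, ValueError):
    """The region's state column has zero variance in the analysed subjects."""


class ContractError(CnvGwasError, ValueError):
    """An operation received input violating its documented precondition."""


class NeutralStateWarning(UserWarning):
    """A segment with copy number 2 was rejected (not a CNV)."""


class MissingMetadataWarning(UserWarning):
    """Optional metadata (e.g. the marker count) is absent; fail-open policy applied."""
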