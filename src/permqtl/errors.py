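"""Exception hierarchy shared across the package."""


class PermqtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PermqtlError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(PermqtlError):
    """Malformed input data (files, matrices, posteriors)."""


class UndefinedStatisticError(PermqtlError):
    """A statistic is undefined for the given input (e.g. monomorphic variant)."""


class EmptyResultError(PermqtlError):
    """An operation produced an empty result that must not pass silently."""


class CollinearityError(PermqtlError):
    """Covariate design matrix is (numerically) rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class StageError(PermqtlError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
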