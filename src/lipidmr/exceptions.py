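"""Exception hierarchy shared across the package."""


class LipidMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LipidMRError):
    """A configuration, column mapping or preset name is invalid."""


class EmptyInputError(LipidMRError):
    """An input table contained no usable rows."""


class EmptySetError(LipidMRError):
    """A filtering step left zero instruments."""


class EmptySelectionError(LipidMRError):
    """No SNP passed the instrument-selection threshold."""


class InsufficientInstrumentsError(LipidMRError):
    """Fewer instruments than the estimator's minimum k."""


class UndefinedRatioError(LipidMRError):
    """A Wald ratio with zero (or degenerate) exposure effect."""


class InvalidSampleSizeError(LipidMRError):
    """Sample size too small for the requested statistic."""


class CollinearityError(LipidMRError):
    """Exposure design matrix is rank deficient."""


class DomainError(LipidMRError):
    """A numeric argument lies outside its mathematical domain."""
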