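"""Exception hierarchy.

Everything derives from :class:`ImputeBenchError` so callers can catch the
package's failures with one clause; the subclasses mirror the failure modes
of the pipeline stages (configuration, missingness mechanism, degenerate
inputs, numerical samplers).
"""


class ImputeBenchError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ImputeBenchError, ValueError):
    """Invalid configuration values (nonpositive sizes, sd <= 0, ...)."""


class MechanismError(ImputeBenchError, ValueError):
    """Missingness mechanism cannot be applied (bad predictor column, ...)."""


class DegenerateDataError(ImputeBenchError, ValueError):
    """Input leaves nothing to work with (zero complete cases, empty column)."""


class CarryError(ImputeBenchError, ValueError):
    """LOCF/LOCB cannot find an observed value to carry."""


class CollinearityError(ImputeBenchError, ValueError):
    """Singular design matrix in a regression-based imputer."""


class SamplerError(ImputeBenchError, RuntimeError):
    """An MCMC/bootstrap sampler produced non-finite draws or kept failing."""


class ValidationError(ImputeBenchError, ValueError):
    """Inconsistent arguments to an analysis routine (length mismatch, ...)."""
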