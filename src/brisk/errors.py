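"""Exception hierarchy shared across the package.

The command-line layer maps these onto exit codes: configuration problems
exit with 2, data problems with 3.
"""


class BriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BriskError):
    """Invalid or incomplete model configuration (parameter tables, schemes,
    hazard coverage declared in config, missing component parameters)."""


class InputError(BriskError):
    """Invalid data supplied at run time (out-of-range covariate, malformed
    row, score outside [0, 1], ...)."""


class CoverageError(ConfigurationError):
    """A lookup fell outside the configured table (hazard ages, family-history
    bands)."""


class UndefinedStatisticError(BriskError):
    """A statistic is requested on input where it is not defined (empty arm,
    zero variance denominator)."""


class FixtureError(BriskError):
    """A packaged reference table failed its self-validation (marginal totals
    do not reproduce the embedded totals)."""
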