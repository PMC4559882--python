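"""Exception hierarchy.

Every failure a caller may want to branch on derives from :class:`MirbayesError`.
The CLI maps these onto exit codes: configuration/parse/integrity problems
exit 2, degenerate or insufficient statistics exit 3.
"""


class MirbayesError(Exception):
    """Base class for all package errors."""


class ParseError(MirbayesError):
    """A cell in an input table could not be parsed; names row and column."""


class IntegrityError(MirbayesError):
    """Structural violation of the cohort schema, e.g. duplicate (sample, assay)."""


class ConfigurationError(MirbayesError):
    """Invalid or inconsistent user configuration."""


class DegenerateDataError(MirbayesError):
    """Data carry no usable variation (all-zero variances, constant class, ...)."""


class InsufficientDataError(MirbayesError):
    """Too few observations for the requested statistic."""


class AuditNotApplicableError(MirbayesError):
    """Session audit requested on data without at least two sessions."""


class InfeasibleThresholdError(MirbayesError):
    """The quadratic decision-threshold equation has no real root."""
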