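"""Exception and warning types shared across the package."""


class CasemixError(Exception):
    """Base class for all casemix errors."""


class SchemaError(CasemixError):
    """A required column is missing or a file does not match the expected layout."""


class ParseError(CasemixError):
    """A cell could not be parsed as a number, or a value is missing."""


class SizeError(CasemixError):
    """A requested subsample exceeds the number of eligible rows."""


class ConfigurationError(CasemixError):
    """An invalid combination of modelling options was requested."""


class DegenerateLabelsError(CasemixError):
    """Membership indicator has a single class; the propensity model is undefined."""


class DegenerateOutcomeError(CasemixError):
    """Outcome has a single class among the (weighted) rows; the fit is undefined."""


class ConvergenceError(CasemixError):
    """An iterative fit failed to converge; no partial estimates are returned."""


class QuasiSeparationWarning(UserWarning):
    """The membership classes are (quasi-)separated; propensities are at the
    boundary and inverse-odds weights will be extreme. Consider ridge > 0 if
    this is not the intended complete-shift behaviour."""


class FitConvergenceWarning(UserWarning):
    """An iterative fit stopped before meeting its tolerance."""
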