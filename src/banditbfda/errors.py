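"""Exception types raised across the package."""


class BanditBFDAError(Exception):
    """Base class for package errors."""


class InvalidParameterError(BanditBFDAError, ValueError):
    """A model or design parameter is outside its admissible range."""


class InvalidInputError(BanditBFDAError, ValueError):
    """Input data violate a precondition (shape, finiteness, grid match)."""


class ConfigurationError(BanditBFDAError, ValueError):
    """A task/run configuration is inconsistent or incomplete."""


class DegenerateLikelihoodError(BanditBFDAError, ArithmeticError):
    """A likelihood assigns zero mass everywhere on the grid."""


class UndefinedEvidenceError(BanditBFDAError, ArithmeticError):
    """A Bayes factor is 0/0 and carries no evidential meaning."""
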