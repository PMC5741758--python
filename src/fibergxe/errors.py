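"""Exception hierarchy for fibergxe."""


class FibergxeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FibergxeError):
    """A delimited-text / VCF input violates the expected layout."""


class DomainError(FibergxeError):
    """A value lies outside its scientific domain (e.g. energy <= 0)."""


class ValidationError(FibergxeError):
    """A dataset violates a structural contract (matched-set layout, panel consistency)."""


class ConvergenceError(FibergxeError):
    """A likelihood fit failed to converge."""


class SeparationError(ConvergenceError):
    """Complete or quasi-complete separation: a coefficient diverges.

    Carries the name of the offending covariate in ``covariate``.
    """

    def __init__(self, covariate: str, message: str | None = None):
        self.covariate = covariate
        super().__init__(message or f"separation detected on covariate {covariate!r}")
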