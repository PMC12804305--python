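"""Exception and warning types shared across the package."""


class BiodistError(Exception):
    """Base class for all package-specific errors."""


class NuclideLookupError(BiodistError, KeyError):
    """Raised when a radionuclide label does not resolve in the database.

    Carries ``suggestions``: the nearest-matching known labels.
    """

    def __init__(self, label: str, suggestions: tuple[str, ...] = ()):
        self.label = label
        self.suggestions = tuple(suggestions)
        msg = f"unknown nuclide {label!r}"
        if self.suggestions:
            msg += f"; nearest matches: {', '.join(self.suggestions)}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class ClockMixError(BiodistError, ValueError):
    """Offset-aware and naive timestamps mixed within one study clock."""


class DecayRangeError(BiodistError, OverflowError):
    """Decay-correction exponent beyond the representable range."""


class StudyValidationError(BiodistError, ValueError):
    """A study bundle failed validation; carries the full report."""

    def __init__(self, report):
        self.report = report
        super().__init__(str(report))


class FitConvergenceError(BiodistError, RuntimeError):
    """Nonlinear decay fit failed to converge; carries initialization info."""


class BiodistWarning(UserWarning):
    """Base warning category for quality/consistency advisories."""


class CountingQualityWarning(BiodistWarning):
    """Replicate scatter, saturation, or low-replicate advisories."""


class RecoveryWarning(BiodistWarning):
    """Activity-recovery diagnostics (e.g. summed %ID exceeding 100%)."""
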