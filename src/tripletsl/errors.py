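"""Exception hierarchy for tripletsl."""


class TripletSLError(Exception):
    """Base class for all package errors."""


class DesignError(TripletSLError, ValueError):
    """Invalid experiment design parameters (e.g. stimulus set not divisible by 3)."""


class GenerationError(TripletSLError, RuntimeError):
    """A randomized construction could not satisfy its constraints."""


class ScoringError(TripletSLError, ValueError):
    """Invalid input to keypress scoring (e.g. unsorted keypress log)."""


class NormingError(TripletSLError, ValueError):
    """z-normalization undefined (zero variance or a single observation)."""


class FitError(TripletSLError, RuntimeError):
    """A statistical model could not be estimated."""


class SpecError(TripletSLError, ValueError):
    """Invalid simulation cohort specification."""


class ValidationError(TripletSLError, ValueError):
    """A dataset bundle failed schema or referential-integrity checks.

    ``issues`` holds an itemized list of human-readable problems.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("bundle validation failed:\n" + "\n".join(f"  - {m}" for m in self.issues))
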