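"""Exception hierarchy for cgmetrics."""


class CgmetricsError(Exception):
    """Base class for all package errors."""


class DialectError(CgmetricsError):
    """A CGM export does not match the declared dialect (missing columns etc.)."""


class EmptyInputError(CgmetricsError):
    """An input yielded zero usable rows."""


class UndefinedMetricsError(CgmetricsError):
    """A metric is undefined for the given input (e.g. all-missing trace)."""


class InvalidProfileError(CgmetricsError):
    """A 24-h step profile has gaps or overlapping segments."""


class DegenerateSampleError(CgmetricsError):
    """A statistical comparison cannot be computed (e.g. zero pooled variance)."""


class CollinearityError(CgmetricsError):
    """The regression design matrix is singular."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class FitError(CgmetricsError):
    """A maximum-likelihood fit failed to converge.

    Carries the optimizer trajectory (list of (params, loglik) tuples) for
    post-mortem inspection.
    """

    def __init__(self, message: str, trajectory=()):
        super().__init__(message)
        self.trajectory = list(trajectory)
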