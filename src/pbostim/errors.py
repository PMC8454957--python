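"""Exception hierarchy.

All package-specific failures derive from :class:`PBOStimError` so callers
can catch domain errors without swallowing programming errors.
"""


class PBOStimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PBOStimError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDriftError(PBOStimError):
    """Proportion correct is exactly 0.5 after edge correction.

    The logit of 0.5 is zero, which forces drift rate v = 0 and leaves the
    boundary separation a = s**2 * L / v undefined.  Callers that want the
    v = 0 convention can catch this and substitute it explicitly.
    """


class ScoringError(PBOStimError):
    """A block cannot be scored (e.g. fewer than two correct responses)."""


class InvalidBaselineError(PBOStimError, ValueError):
    """Baseline drift rate is non-positive; normalized score undefined."""


class CodebookError(PBOStimError, KeyError):
    """Unknown blinding code or parameters outside the codebook's grid."""


class InvalidHyperparameterError(PBOStimError, ValueError):
    """A Gaussian-process hyperparameter is non-positive or out of bounds."""


class DegenerateDataError(PBOStimError):
    """Training outputs have zero variance; standardization is undefined."""


class NumericalFailureError(PBOStimError):
    """Covariance factorization failed even after jitter."""


class ConfigurationError(PBOStimError, ValueError):
    """A protocol or benchmark configuration is internally inconsistent."""


class ProtocolError(PBOStimError):
    """The sequential experimental protocol was violated."""


class ProtocolComplete(PBOStimError):
    """Stop signal: the pre-set stopping criterion has been reached."""


class SplitError(PBOStimError):
    """A participant-level train/test split cannot be formed."""
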