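"""Exception types raised across the pipeline."""


class AngiosigError(Exception):
    """Base class for package errors."""


class ConfigurationError(AngiosigError):
    """A simulation or pipeline configuration is invalid or infeasible."""


class InputError(AngiosigError):
    """Input data violates a precondition (labels, shapes, ranges)."""


class NormalizationError(AngiosigError):
    """Size-factor normalization is undefined for the given counts."""


class EstimationError(AngiosigError):
    """A statistical fit failed (non-convergence, separation, degeneracy)."""


class ScoringError(AngiosigError):
    """A signature cannot be scored on the given expression matrix."""
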