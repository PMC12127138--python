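"""Exception types shared across the package."""


class DeadRecoveryError(Exception):
    """Base class for all package-specific errors."""


class EncodingError(DeadRecoveryError):
    """Raised for an unknown encoding or an undefined recoding path."""


class ValidationError(DeadRecoveryError):
    """Raised when data violate a structural invariant (bad codes,
    recovery before release, inconsistent auxiliaries, ...)."""


class ConvergenceError(DeadRecoveryError):
    """Raised when the simulation study exhausts its resimulation budget
    without reaching the requested number of converged replicates."""
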