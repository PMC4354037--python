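"""Exception types shared across kinflow modules."""


class KinflowError(Exception):
    """Base class for all kinflow-specific errors."""


class ParameterError(KinflowError, ValueError):
    """A rate constant or concentration is invalid (negative, non-finite, inconsistent)."""


class InputError(KinflowError, ValueError):
    """Malformed user input (bad sequence alphabet, empty series, shape mismatch...)."""


class DegenerateInputError(KinflowError, ValueError):
    """Input is structurally valid but the requested quantity is undefined for it."""


class NumericalError(KinflowError, RuntimeError):
    """An iterative numerical procedure failed to converge; carries diagnostics."""


class FitError(KinflowError, RuntimeError):
    """Nonlinear regression failed or the model is unidentifiable on the data."""
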