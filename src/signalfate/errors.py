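"""Exception hierarchy shared across the package."""


class SignalFateError(Exception):
    """Base class for all package-specific errors."""


class DegenerateKineticsError(SignalFateError):
    """The reaction kinetics admit no unique homogeneous root (B == A)."""


class CFLViolationError(SignalFateError):
    """Requested explicit time step exceeds the diffusion stability bound."""


class InvalidSpecError(SignalFateError):
    """A profile or parameter specification is internally inconsistent."""


class InvalidGeometryError(SignalFateError):
    """Lattice geometry is not a rectangular grid."""


class ExtinctSystemError(SignalFateError):
    """All reaction propensities are zero; the stochastic system is frozen."""


class OutOfRangeError(SignalFateError):
    """A signal value lies outside the admissible (0, 5) scale."""


class NonConvergenceError(SignalFateError):
    """The population loop failed to converge within the iteration cap."""

    def __init__(self, message, diff_trace=None):
        super().__init__(message)
        self.diff_trace = list(diff_trace) if diff_trace is not None else []


class InvalidCodeError(SignalFateError):
    """A cell-type code outside 1..6 was encountered."""


class MalformedFileError(SignalFateError):
    """A CSV/config file could not be parsed into the expected shape."""


class InsufficientInformationError(SignalFateError):
    """Too few informative pixels to classify a reconstructed signal plane."""


class UnknownKindError(SignalFateError):
    """Unknown fixture or preset name."""


class ShapeMismatchError(SignalFateError):
    """Two grids that must share a shape do not."""
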