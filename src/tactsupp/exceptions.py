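"""Exception hierarchy for the tactsupp pipeline."""


class TactsuppError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(TactsuppError):
    """Experimental design parameters are inconsistent or non-positive."""


class InsufficientHistoryError(TactsuppError):
    """Adaptive stimulus scheduling asked for more onset history than available."""


class NoMovementError(TactsuppError):
    """Position trace never leaves the start position by more than the threshold."""


class NoReturnError(TactsuppError):
    """Position trace never returns to within the threshold of the start position."""


class WindowError(TactsuppError):
    """Requested analysis window lies (partly) outside the trace extent."""


class InsufficientSamplesError(TactsuppError):
    """Too few samples in a window for the requested statistic."""


class ResampleRequiredError(TactsuppError):
    """Operation requires uniform sampling but the trace is non-uniform."""


class UnsupportedGridError(TactsuppError):
    """Amplitude grid does not match the binning scheme."""


class InsufficientNoiseError(TactsuppError):
    """Fewer noise trials than bins in a condition."""


class EmptyCellError(TactsuppError):
    """A signal-detection cell has zero signal or noise trials."""


class MustCorrectError(TactsuppError):
    """Hit or false-alarm rate at 0/1 passed to the z-transform without correction."""


class NoThresholdError(TactsuppError):
    """Psychometric data carry no information about the 50% point."""


class SchemaError(TactsuppError):
    """A trial table is missing required columns or has malformed rows."""


class SingularDesignError(TactsuppError):
    """Fixed-effect design matrix is rank deficient."""
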