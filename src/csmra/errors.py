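"""Exception types raised across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(RuntimeError):
    """Sampling-rate calibration could not bracket the requested rate.

    Carries the bracketing rates so the caller can see how far off the
    achievable range was.
    """

    def __init__(self, message, rate_lo=None, rate_hi=None):
        super().__init__(message)
        self.rate_lo = rate_lo
        self.rate_hi = rate_hi


class NumericError(RuntimeError):
    """Non-finite values were produced during an iterative computation."""


class NoKeypointsError(RuntimeError):
    """Keypoint detection found nothing on the reference image."""
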