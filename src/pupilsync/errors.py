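"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter combination violates a stated design constraint."""


class UnusableSignalError(RuntimeError):
    """A pupil trace cannot be processed (e.g. no valid samples)."""


class InsufficientDataError(RuntimeError):
    """Not enough data for the requested computation (too short, too few units)."""


class ResolutionError(ValueError):
    """A frequency band contains no spectral bins at the available resolution."""
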