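"""Exception hierarchy for the cytomito pipeline.

Every stage raises a subclass of :class:`CytomitoError` so that the pipeline
driver can abort with the stage name while preserving partial results.
"""


class CytomitoError(Exception):
    """Base class for all cytomito errors."""


class FormatError(CytomitoError):
    """Input file could not be parsed in the requested format."""


class ChannelNotFoundError(CytomitoError):
    """A named channel is absent from the file header."""

    def __init__(self, channel: str, available: list[str]):
        self.channel = channel
        self.available = list(available)
        super().__init__(
            f"channel {channel!r} not found; available channels: {self.available}"
        )


class SampleSizeError(CytomitoError):
    """Too few events for a statistical operation."""


class DegenerateInputError(CytomitoError):
    """Input has no usable variation (e.g. constant signal)."""


class PeakDetectionError(CytomitoError):
    """No qualifying density mode was found.

    Carries the density profile for diagnostics.
    """

    def __init__(self, message: str, profile=None):
        self.profile = profile
        super().__init__(message)


class GatingError(CytomitoError):
    """A gate selected no events."""


class RegressionError(CytomitoError):
    """Regression could not be fit (e.g. degenerate predictor variance)."""


class ContractError(CytomitoError):
    """Mismatched inputs to an estimator (e.g. shifts from different ploidy peaks)."""


class ConfigError(CytomitoError):
    """Run configuration is invalid or incomplete."""


class SpecError(CytomitoError):
    """A synthetic population spec is invalid."""
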