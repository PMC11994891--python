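"""Exception hierarchy for satquant.

Every error raised deliberately by the package derives from
:class:`SatquantError`, so callers (notably the CLI batch runner) can
isolate per-section failures without masking programming errors.
"""


class SatquantError(Exception):
    """Base class for all satquant errors."""


class FormatError(SatquantError):
    """An input file has a bit depth or layout with no lossless 8-bit mapping."""


class DimensionError(SatquantError):
    """An image is empty or its dimensions are inconsistent with another's."""


class ParameterError(SatquantError):
    """A filter or morphology parameter is out of its admissible range."""


class DegenerateHistogramError(SatquantError):
    """A histogram has too little structure for the requested threshold method."""


class NotBimodalError(DegenerateHistogramError):
    """Iterative smoothing never produced a two-mode histogram (Intermodes)."""


class ChannelProcessingError(SatquantError):
    """A channel chain failed; carries the channel name for context."""

    def __init__(self, channel: str, message: str):
        self.channel = channel
        super().__init__(f"[{channel}] {message}")


class PlacementError(SatquantError):
    """Nucleus placement could not satisfy the spacing constraint."""


class UndefinedFitError(SatquantError):
    """The manual counts have zero variance; the regression is undefined."""
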