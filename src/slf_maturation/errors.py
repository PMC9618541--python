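"""Exception hierarchy shared across the pipeline."""


class SlfError(Exception):
    """Base class for all package errors."""


class FormatError(SlfError):
    """A file does not conform to the expected on-disk format."""


class CorruptFileError(FormatError):
    """A file is recognisably the right format but structurally damaged."""


class GradientError(SlfError):
    """Invalid or inconsistent gradient table."""


class LayoutError(SlfError):
    """A phantom layout cannot be constructed as requested."""


class SelectionError(SlfError):
    """Streamline selection was asked to use an unknown ROI or rule."""


class SamplingError(SlfError):
    """Metric sampling failed (degenerate streamline, empty bundle...)."""


class FitError(SlfError):
    """A model fit cannot be performed on the given data."""


class StatsError(SlfError):
    """A statistic is undefined or a reference is degenerate."""
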