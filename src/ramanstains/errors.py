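"""Exception hierarchy for the ramanstains toolkit.

All library errors derive from :class:`RamanStainsError` so callers (and the
CLI) can distinguish data/usage problems from genuine bugs.
"""


class RamanStainsError(Exception):
    """Base class for all ramanstains errors."""


class FormatError(RamanStainsError):
    """A spectrum file could not be parsed (bad line, bad dialect)."""


class TooShortError(FormatError):
    """A spectrum has fewer points than the minimum (8)."""


class DuplicateAxisError(FormatError):
    """A spectrum file contains duplicate Raman-shift values."""


class AxisError(RamanStainsError):
    """Axis mismatch, non-uniformity, or out-of-range resampling."""


class ParameterError(RamanStainsError):
    """An operation was called with invalid parameters."""


class DegenerateSpectrumError(RamanStainsError):
    """A spectrum is degenerate for the requested operation (e.g. zero area)."""


class InsufficientReplicatesError(RamanStainsError):
    """Too few spectra in a set for the requested statistic."""


class EmptyInputError(RamanStainsError):
    """An empty spectrum set or library was supplied."""


class NoCommonRangeError(AxisError):
    """Spectra in a set have no overlapping Raman-shift range."""
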