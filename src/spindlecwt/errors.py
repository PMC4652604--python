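"""Exception hierarchy shared by all spindlecwt modules."""


class SpindleError(Exception):
    """Base class for all spindlecwt errors."""


class FormatError(SpindleError):
    """A file could not be read in the expected format."""


class ParseError(SpindleError):
    """A text file (hypnogram, events) contains an unparseable entry."""


class ValidationError(SpindleError):
    """A domain object violates one of its invariants."""


class UnsupportedError(SpindleError):
    """The input is valid but outside what the method supports."""


class InsufficientDataError(SpindleError):
    """Not enough clean signal (or too few pairs) to estimate a quantity."""


class ShortSegmentError(SpindleError):
    """Signal segment shorter than the analysis kernel."""


class EmptySelectionError(SpindleError):
    """Stage/mask selection leaves no samples to analyse."""


class ConfigurationError(SpindleError):
    """Run configuration is inconsistent with the supplied data."""


class GenerationError(SpindleError):
    """Synthetic-data spec cannot be realised (e.g. irresolvable overlaps)."""


class IterationCapError(SpindleError):
    """An open-ended resampling loop hit its iteration cap."""
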