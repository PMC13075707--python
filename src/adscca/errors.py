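"""Exception hierarchy used across the package."""


class AdsccaError(Exception):
    """Base class for package errors."""


class InvalidConfigError(AdsccaError, ValueError):
    """A configuration value violates its documented constraints."""


class ShapeError(AdsccaError, ValueError):
    """Array dimensions do not match what an operation requires."""


class ParseError(AdsccaError, ValueError):
    """A file could not be parsed; message names the offending line/field."""


class SampleMismatchError(AdsccaError, ValueError):
    """The two modalities do not cover the same samples."""


class EmptyIntersectionError(AdsccaError, ValueError):
    """Gene harmonization produced an empty gene set."""


class InsufficientEventsError(AdsccaError, ValueError):
    """Too few observed events for survival model fitting."""


class BatchTooSmallError(AdsccaError, ValueError):
    """A mini-batch is too small for correlation/variance terms."""
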