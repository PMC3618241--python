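"""Exception hierarchy for zdsearch."""


class ZDSearchError(Exception):
    """Base class for all zdsearch errors."""


class ParameterError(ZDSearchError, ValueError):
    """A parameter is outside its documented domain."""


class EmptySupportError(ZDSearchError):
    """A voxel grid with no nonzero voxel cannot be normalized."""


class IndexConstraintError(ParameterError):
    """An (n, l, m) triple violates 0 <= l <= n, n-l even, |m| <= l."""


class DimensionMismatchError(ZDSearchError, ValueError):
    """Vectors of different dimensionality were combined."""


class IndexBuildError(ZDSearchError):
    """An index cannot be built under the given parameters."""


class DescriptorParseError(ZDSearchError):
    """A descriptor table file is malformed."""


class IndexFormatError(ZDSearchError):
    """A persisted index file is unreadable or has a wrong version."""
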