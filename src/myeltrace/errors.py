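"""Exception hierarchy.

Every error raised by the library derives from :class:`MyelTraceError`, so the
command-line layer can distinguish user/input problems (exit code 1) from
genuine bugs (exit code 2).
"""


class MyelTraceError(Exception):
    """Base class for all errors raised by myeltrace."""


class UnsupportedImageError(MyelTraceError):
    """Input raster is not 8-bit single- or three-channel."""


class ThresholdRangeError(MyelTraceError, ValueError):
    """Threshold outside the 8-bit intensity range [0, 255]."""


class StrokeBoundsError(MyelTraceError, ValueError):
    """A stroke vertex falls outside the image; carries the stroke index."""

    def __init__(self, stroke_index: int, vertex, shape):
        self.stroke_index = stroke_index
        super().__init__(
            f"stroke {stroke_index}: vertex {vertex} outside image of "
            f"height={shape[0]}, width={shape[1]}"
        )


class NonBinaryMaskError(MyelTraceError, ValueError):
    """Contour extraction requires a strictly two-valued {0, 255} mask."""


class DegenerateGeometryError(MyelTraceError, ValueError):
    """Polygon with fewer than 3 effective vertices or zero area."""


class NestingViolationError(MyelTraceError, ValueError):
    """Inner area exceeds outer area in a g-ratio computation."""


class AmbiguousNestingError(MyelTraceError):
    """Two contours of the same class nest within one candidate parent."""

    def __init__(self, parent_id, child_ids):
        self.parent_id = parent_id
        self.child_ids = list(child_ids)
        super().__init__(
            f"contours {self.child_ids} all nest within contour {parent_id}; "
            "cannot assign a unique inner feature"
        )


class EmptyCountError(MyelTraceError, ValueError):
    """Percentage requested from a zero-total myelination count."""


class SessionError(MyelTraceError):
    """Session file unreadable or structurally invalid."""


class SessionVersionError(SessionError):
    """Session file schema_version not supported by this build."""


class PhantomLayoutError(MyelTraceError, ValueError):
    """Synthetic fibers overlap without an explicit touching intent."""


class ConfigError(MyelTraceError, ValueError):
    """Pipeline configuration fails validation."""
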