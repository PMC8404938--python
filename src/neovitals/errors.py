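"""Exception hierarchy.

All validation failures (bad boxes, bad bands, bad configs) raise plain
``ValueError`` so they compose with numpy/pandas call sites; the classes here
mark conditions a pipeline caller may want to catch and recover from.
"""


class NeovitalsError(Exception):
    """Base class for recoverable pipeline conditions."""


class VideoDecodeError(NeovitalsError):
    """The media backend could not decode the input file."""


class EmptyVideoError(NeovitalsError):
    """The input decoded to zero frames."""


class DetectionError(NeovitalsError):
    """An ROI detector plugin failed to return a bounding box."""


class InsufficientPeaksError(NeovitalsError):
    """Fewer than two peaks were found; no cycle length is defined."""


class NoDominantFrequencyError(NeovitalsError):
    """The spectrum is all-zero after DC removal; no dominant bin exists."""
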