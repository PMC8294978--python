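"""Package-wide exception types.

All inherit from :class:`OctanvError` so callers can catch the package's
failures with one clause; most also inherit ``ValueError`` because they
signal invalid inputs.
"""

from __future__ import annotations


class OctanvError(Exception):
    """Base class for all errors raised by octanv."""


class ParameterError(OctanvError, ValueError):
    """Invalid parameter values (non-positive dimensions, bad ranges)."""


class GeometryError(OctanvError, ValueError):
    """Geometry outside its allowed domain (tree outside grid, slab
    outside volume, ROI below the ILM)."""


class ScheduleError(OctanvError, KeyError):
    """A visit week that does not appear in the perfusion schedule."""


class DegenerateRoiError(OctanvError, ValueError):
    """An ROI that selects no pixels or has fewer than 3 vertices."""


class FormatError(OctanvError, ValueError):
    """Unsupported file layout or ROI subtype."""


class EndpointError(OctanvError, ValueError):
    """Endpoint selection failed (no visit inside the posttreatment
    window, degenerate baseline)."""
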