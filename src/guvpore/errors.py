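"""Exception hierarchy for guvpore.

All package-specific failures derive from :class:`GuvPoreError` so callers can
catch pipeline-level problems with a single except clause while letting
programming errors (TypeError, ValueError from bad arguments) propagate.
"""

from __future__ import annotations


class GuvPoreError(Exception):
    """Base class for all guvpore-specific errors."""


class ShapeOutOfBounds(GuvPoreError):
    """A vesicle shape does not fit inside the image with the required margin."""


class SimulationCollapse(GuvPoreError):
    """The efflux ODE drove the vesicle radius down to the pore radius."""

    def __init__(self, time_s: float, message: str | None = None):
        self.time_s = time_s
        super().__init__(message or f"vesicle collapsed onto the pore at t = {time_s:.6g} s")


class NoContourError(GuvPoreError):
    """No closed vesicle contour could be recovered from a frame."""


class DegenerateContourError(GuvPoreError):
    """A polygon with fewer than 3 vertices or zero area was supplied."""


class InsufficientPixelsError(GuvPoreError):
    """Interior or exterior sampling region for the contrast index is empty."""


class EmptyTrackError(GuvPoreError):
    """Every frame of a movie failed contour detection."""


class WindowEmptyError(GuvPoreError):
    """A pre- or post-pulse frame window contains only gap frames."""


class InsufficientDataError(GuvPoreError):
    """Too few samples to classify a contrast trace."""


class InvalidFieldError(GuvPoreError):
    """A negative electric-field strength was supplied."""


class FitError(GuvPoreError):
    """A least-squares fit failed to converge from every starting point.

    Carries the best attempt (may be ``None``) so callers can inspect it.
    """

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class ConfigError(GuvPoreError):
    """A pipeline configuration references missing inputs or is inconsistent."""
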