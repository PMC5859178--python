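"""Closed-polygon geometry shared by the synthetic renderer and the tracker.

Polygons are (N, 2) float arrays of vertices. They are treated as implicitly
closed: the segment from the last vertex back to the first is always included,
and a duplicated closing vertex is tolerated.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateContourError

__all__ = [
    "as_closed_polygon",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "form_factor",
]


def as_closed_polygon(vertices) -> np.ndarray:
    """Return an (N, 2) array without a duplicated closing vertex.

    Raises
    ------
    DegenerateContourError
        If fewer than 3 distinct vertices remain.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise DegenerateContourError(f"expected an (N, 2) vertex array, got shape {v.shape}")
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3:
        raise DegenerateContourError(f"polygon has only {len(v)} distinct vertices")
    return v


def polygon_area(vertices) -> float:
    """Unsigned enclosed area by the shoelace formula."""
    v = as_closed_polygon(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def polygon_perimeter(vertices) -> float:
    """Arc length of the closed polygon boundary."""
    v = as_closed_polygon(vertices)
    d = np.roll(v, -1, axis=0) - v
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def polygon_centroid(vertices) -> tuple[float, float]:
    """Centroid of the enclosed region (not the vertex mean)."""
    v = as_closed_polygon(vertices)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-300:
        raise DegenerateContourError("polygon has zero area")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return cx, cy


def form_factor(area: float, perimeter: float) -> float:
    """Circularity index 4*pi*A / P**2: 1 for a circle, < 1 otherwise."""
    if perimeter <= 0:
        raise DegenerateContourError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2
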