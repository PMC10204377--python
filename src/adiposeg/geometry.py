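"""Polygon utilities shared by the contour, partition and area code.

Contours are (n, 2) float arrays of (row, col) coordinates, implicitly
closed.  Orientation is normalised to counter-clockwise in (col, row)
axes, i.e. positive shoelace signed area.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed (row, col) polygon in px^2."""
    r = points[:, 0]
    c = points[:, 1]
    return 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))


def polygon_area(points: np.ndarray) -> float:
    return abs(signed_area(points))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the polygon with positive shoelace orientation."""
    if signed_area(points) < 0:
        return points[::-1].copy()
    return points


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to `n` points at uniform arc length."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(pts[:1], n, axis=0)
    t = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(t, s, closed[:, 0])
    cols = np.interp(t, s, closed[:, 1])
    return np.column_stack([rows, cols])


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Point-in-polygon test; points exactly on an edge count as inside.

    Boundary inclusion is realised by accepting a point if it tests inside
    for either sign of matplotlib's `radius` boundary offset, which makes
    the test independent of polygon orientation.
    """
    path = Path(np.asarray(polygon, dtype=float))
    pts = np.asarray(points, dtype=float)
    eps = 1e-9
    return path.contains_points(pts, radius=eps) | path.contains_points(pts, radius=-eps)


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centres fall inside the polygon.

    Only pixels inside the polygon's bounding box are tested, so the cost
    scales with the polygon, not the image.
    """
    poly = np.asarray(polygon, dtype=float)
    r0 = max(int(np.floor(poly[:, 0].min())), 0)
    r1 = min(int(np.ceil(poly[:, 0].max())) + 1, shape[0])
    c0 = max(int(np.floor(poly[:, 1].min())), 0)
    c1 = min(int(np.ceil(poly[:, 1].max())) + 1, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    inside = points_in_polygon(pts, poly)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


def polygon_perimeter_px(points: np.ndarray) -> float:
    closed = np.vstack([points, points[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
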