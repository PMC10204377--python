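"""Two-stage active-contour (snake) detection of the abdominal wall.

A snake is a closed energy-minimising spline: internal tension
(alpha |v'|^2) and rigidity (beta |v''|^2) terms keep it smooth while an
external image force pulls it onto edges and a balloon pressure drives
it through featureless regions.  The discretisation is the classic
semi-implicit one: the internal energy gives a cyclic pentadiagonal
system solved once per iteration, the external and balloon forces are
applied explicitly.

Stage one shrinks the (slightly dilated) convex hull of the body mask
onto the skin boundary.  Stage two shrinks a copy of the outer contour
through the subcutaneous fat ring until it locks onto the fat/muscle
transition — the inner abdominal wall — using the gradient of a
fat-likelihood image as its edge map.  Computing edge maps on indicator
images rather than raw intensities is what lets one contour engine serve
both CT and MR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .body_mask import BodyMask
from .image import AbdominalImage, Modality
from .preprocess import ThresholdSpec
from . import geometry

MIN_CONTOUR_AREA_PX2 = 25.0
EDGE_SIGMA_PX = 2.0


class ContourCollapseError(RuntimeError):
    """Raised when an evolving contour shrinks below the minimum area."""


@dataclass
class Contour:
    """Closed simple polygon, (n, 2) array of (row, col), CCW orientation."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 16:
            raise ValueError("a contour needs an (n>=16, 2) point array")
        pts = geometry.ensure_ccw(pts)
        if geometry.polygon_area(pts) <= 0:
            raise ValueError("contour encloses no area")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def area_px2(self) -> float:
        return geometry.polygon_area(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def scaled(self, factor: float) -> "Contour":
        """Contour scaled about its centroid."""
        c = self.centroid()
        return Contour(c + factor * (self.points - c))

    def resampled(self, n: int) -> "Contour":
        return Contour(geometry.resample_closed(self.points, n))


@dataclass
class WallContours:
    outer: Contour
    inner: Contour

    def __post_init__(self) -> None:
        if self.inner.area_px2() >= self.outer.area_px2():
            raise ValueError("inner contour area must be smaller than outer")
        inside = geometry.points_in_polygon(self.inner.points, self.outer.points)
        if not inside.all():
            raise ValueError(
                f"{int((~inside).sum())} inner contour points fall outside the outer contour"
            )


@dataclass(frozen=True)
class SnakeParams:
    """Weights and numerics of the snake solver.

    alpha, beta weight tension and rigidity; gamma is the implicit time
    step; balloon is the pressure along the outward normal (negative
    shrinks); edge_weight scales the attraction to the [0, 1]-normalised
    edge map; evolution stops when the mean point displacement per
    iteration drops below tol (px) or after max_iter iterations.
    """

    alpha: float = 0.05
    beta: float = 0.5
    gamma: float = 1.0
    balloon: float = -0.3
    edge_weight: float = 4.0
    max_iter: int = 500
    tol: float = 0.05
    n_points: int = 200

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")


DEFAULT_OUTER_PARAMS = SnakeParams(balloon=-0.3, edge_weight=4.0)
DEFAULT_INNER_PARAMS = SnakeParams(balloon=-0.5, edge_weight=2.0)

INNER_START_SCALE = 0.98


def _internal_matrix_inverse(n: int, params: SnakeParams) -> np.ndarray:
    """(I - gamma*A)^-1 for the cyclic tension/rigidity operator A."""
    a, b = params.alpha, params.beta
    row = np.zeros(n)
    # A = alpha * D2 - beta * D4 acting on a closed curve
    row[0] = -2.0 * a - 6.0 * b
    row[1] = row[-1] = a + 4.0 * b
    row[2] = row[-2] = -b
    A = np.empty((n, n))
    for i in range(n):
        A[i] = np.roll(row, i)
    return np.linalg.inv(np.eye(n) - params.gamma * A)


def _outward_normals(pts: np.ndarray) -> np.ndarray:
    """Unit outward normals of a closed polygon (orientation-checked)."""
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norm = np.column_stack([tang[:, 1], -tang[:, 0]])
    lengths = np.linalg.norm(norm, axis=1)
    lengths[lengths == 0] = 1.0
    norm /= lengths[:, None]
    centroid = pts.mean(axis=0)
    outward = (norm * (pts - centroid)).sum() >= 0
    return norm if outward else -norm


def evolve_snake(init: Contour, edge_map: np.ndarray, params: SnakeParams) -> Contour:
    """Evolve a snake on an edge map until convergence.

    The edge map is normalised to [0, 1]; the external force is its
    gradient (ascent toward edges), sampled at the snake points by
    bilinear interpolation.  Points are resampled to uniform arc-length
    spacing every iteration so the balloon pressure stays isotropic.
    The solver contains no randomness: identical inputs give identical
    contours.
    """
    edge = np.asarray(edge_map, dtype=float)
    peak = edge.max()
    if peak > 0:
        edge = edge / peak
    gr, gc = np.gradient(edge)

    pts = geometry.resample_closed(init.points, params.n_points)
    inv = _internal_matrix_inverse(params.n_points, params)
    nrows, ncols = edge.shape

    for _ in range(params.max_iter):
        force = np.zeros_like(pts)
        if params.edge_weight != 0:
            fr = map_coordinates(gr, pts.T, order=1, mode="nearest")
            fc = map_coordinates(gc, pts.T, order=1, mode="nearest")
            force += params.edge_weight * np.column_stack([fr, fc])
        if params.balloon != 0:
            force += params.balloon * _outward_normals(pts)

        new_pts = inv @ (pts + params.gamma * force)
        new_pts[:, 0] = np.clip(new_pts[:, 0], 0, nrows - 1)
        new_pts[:, 1] = np.clip(new_pts[:, 1], 0, ncols - 1)

        displacement = float(np.linalg.norm(new_pts - pts, axis=1).mean())
        pts = geometry.resample_closed(new_pts, params.n_points)

        if geometry.polygon_area(pts) < MIN_CONTOUR_AREA_PX2:
            raise ContourCollapseError(
                f"contour collapsed below {MIN_CONTOUR_AREA_PX2} px^2"
            )
        if displacement < params.tol:
            break

    return Contour(pts)


def _refine_on_ridge(contour: Contour, edge_map: np.ndarray, params: SnakeParams) -> Contour:
    """Re-settle a converged snake with the balloon pressure mostly released.

    The main evolution needs enough pressure to cross featureless tissue,
    which leaves the equilibrium a little inside the edge ridge (the snake
    stops where attraction balances pressure, on the ridge flank).  A short
    second pass at one fifth of the pressure lets the contour relax onto
    the ridge crest without drifting through weak edges.
    """
    relaxed = replace(params, balloon=params.balloon * 0.2, max_iter=min(params.max_iter, 200))
    return evolve_snake(contour, edge_map, relaxed)


def _mask_edge_map(mask: np.ndarray) -> np.ndarray:
    """Gradient-magnitude edge map of a smoothed binary mask."""
    smooth = gaussian_filter(mask.astype(float), EDGE_SIGMA_PX)
    gr, gc = np.gradient(smooth)
    return np.hypot(gr, gc)


def _convex_hull_polygon(mask: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    pts = np.column_stack(np.nonzero(mask)).astype(float)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def detect_outer_contour(
    image: AbdominalImage,
    body: BodyMask,
    params: SnakeParams = DEFAULT_OUTER_PARAMS,
) -> Contour:
    """Skin boundary: shrink the dilated convex hull onto the body-mask edge."""
    mask = body.mask
    hull = _convex_hull_polygon(mask)
    centroid = hull.mean(axis=0)
    radial = hull - centroid
    lengths = np.linalg.norm(radial, axis=1)
    lengths[lengths == 0] = 1.0
    init_pts = hull + 2.0 * radial / lengths[:, None]  # dilate 2 px outward
    init = Contour(geometry.resample_closed(init_pts, params.n_points))
    edge = _mask_edge_map(mask)
    contour = evolve_snake(init, edge, params)
    return _refine_on_ridge(contour, edge, params)


def fat_likelihood(
    image: AbdominalImage,
    body: BodyMask,
    threshold_spec: ThresholdSpec | None = None,
) -> np.ndarray:
    """Fat-or-background indicator whose gradient marks the inner wall.

    Inside the body the map is the modality's fat indicator (CT
    Hounsfield window, MR fraction-of-max threshold); outside the body
    it is set to 1.  With a subcutaneous fat ring present the skin
    boundary is then edge-free (air and fat both map to 1) and the first
    transition met travelling inward is fat -> muscle, exactly where the
    inner abdominal wall begins.  Without any subcutaneous fat the body
    boundary itself provides the edge, so the inner contour degenerates
    to the outer one instead of collapsing.
    """
    spec = threshold_spec or (
        ThresholdSpec.ct_default()
        if image.modality is Modality.CT
        else ThresholdSpec.mr_default()
    )
    if spec.modality is not image.modality:
        raise ValueError(f"threshold spec is for {spec.modality}, image is {image.modality}")
    lo, hi = spec.resolve(image, body.mask)
    fat = (image.pixels >= lo) & (image.pixels <= hi)
    return np.where(body.mask, fat.astype(float), 1.0)


def detect_inner_contour(
    image: AbdominalImage,
    outer: Contour,
    params: SnakeParams = DEFAULT_INNER_PARAMS,
    body: BodyMask | None = None,
    threshold_spec: ThresholdSpec | None = None,
) -> Contour:
    """Inner abdominal wall: shrink the outer contour to the fat/muscle edge."""
    if body is None:
        mask = geometry.polygon_mask(outer.points, image.shape)
        body = BodyMask(mask=mask, kind="outer_body")
    likelihood = fat_likelihood(image, body, threshold_spec)
    smooth = gaussian_filter(likelihood, EDGE_SIGMA_PX)
    gr, gc = np.gradient(smooth)
    edge = np.hypot(gr, gc)

    init = outer.scaled(INNER_START_SCALE).resampled(params.n_points)
    inner = evolve_snake(init, edge, params)
    inner = _refine_on_ridge(inner, edge, params)
    if inner.area_px2() >= outer.area_px2():
        raise RuntimeError("inner contour did not shrink inside the outer contour")
    # numerical guard: pull stray points back inside the outer polygon
    pts = inner.points
    for _ in range(20):
        inside = geometry.points_in_polygon(pts, outer.points)
        if inside.all():
            break
        centroid = pts.mean(axis=0)
        pts = pts.copy()
        pts[~inside] = centroid + 0.99 * (pts[~inside] - centroid)
    else:
        raise RuntimeError("inner contour escaped the outer contour")
    return Contour(pts)
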