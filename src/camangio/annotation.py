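"""Vessel annotation: spline interpolation, snake segmentation, skeletons.

Three ways to turn user seeds on the vessel-augmented (virtual
angiography) image into geometry:

* manual: interpolate ordered click points with a periodic (closed
  boundary) or natural (open microvessel curve) cubic spline;
* semi-automatic CAM-vessel boundary: evolve an active contour (snake)
  from the outer contour of a rough ROI mask toward strong image edges;
* semi-automatic microvessels: thin a rough vessel-area mask to its
  one-pixel skeleton, prune short spurs, and split it into centerline
  polylines at junctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from skimage import measure, morphology
from skimage.filters import gaussian
from skimage.segmentation import active_contour

from .cine_io import PointAnnotation, RoiMask
from .exceptions import ValidationError

__all__ = [
    "VesselBoundary",
    "CenterlineSet",
    "SnakeParams",
    "interpolate_boundary",
    "interpolate_curve",
    "snake_segment",
    "skeletonize_mask",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VesselBoundary:
    """A closed smooth boundary of a large CAM vessel."""

    curve: np.ndarray  # (K, 2) closed polygon vertices, (row, col)
    source: str = "manual"  # "manual" | "snake"
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=np.float64)
        if self.curve.ndim != 2 or self.curve.shape[1] != 2:
            raise ValidationError("boundary curve must be (K, 2) points")
        if self.curve.shape[0] < 3:
            raise ValidationError("boundary curve needs at least 3 points")

    @property
    def area(self) -> float:
        """Enclosed area by the shoelace formula (absolute value)."""
        r, c = self.curve[:, 0], self.curve[:, 1]
        return 0.5 * abs(float(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))))


@dataclass
class CenterlineSet:
    """A set of open polyline microvessel centerlines.

    ``junctions`` holds merged skeleton junction nodes (branch points)
    when the set was derived from a skeleton; for manual curve sets it is
    None and branch points are inferred from shared endpoints.
    """

    curves: List[np.ndarray]
    source: str = "manual"  # "manual" | "skeleton"
    junctions: Optional[List[Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        cleaned = []
        for curve in self.curves:
            curve = np.asarray(curve, dtype=np.float64)
            if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 2:
                raise ValidationError("each centerline needs >= 2 (row, col) points")
            cleaned.append(curve)
        self.curves = cleaned


@dataclass
class SnakeParams:
    """Active-contour parameters (all exposed in the run config).

    alpha
        Elasticity weight: penalizes contour length.
    beta
        Rigidity weight: penalizes curvature.
    sigma_px
        Gaussian pre-smoothing of the display image feeding the edge
        (negative gradient magnitude) external energy.
    n_points
        Number of contour points the ROI outline is resampled to.
    max_iter, tol
        Iteration cap and the convergence threshold on mean point
        displacement per iteration, in pixels.
    """

    n_points: int = 200
    alpha: float = 0.015
    beta: float = 10.0
    sigma_px: float = 2.0
    max_iter: int = 2500
    tol: float = 0.1
    w_edge: float = 2.0
    w_line: float = 0.0
    gamma: float = 0.01

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValidationError("n_points must be >= 8")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("max_iter >= 1 and tol > 0 required")
        if self.alpha < 0 or self.beta < 0 or self.sigma_px < 0:
            raise ValidationError("alpha, beta, sigma_px must be >= 0")


# ---------------------------------------------------------------------------
# Manual annotation: interpolating splines through click points
# ---------------------------------------------------------------------------

def _dedupe_consecutive(points: np.ndarray, closed: bool) -> np.ndarray:
    """Collapse duplicate consecutive points (warns); keeps order."""
    keep = [0]
    for i in range(1, len(points)):
        if not np.allclose(points[i], points[keep[-1]]):
            keep.append(i)
    if closed and len(keep) > 1 and np.allclose(points[keep[-1]], points[0]):
        keep.pop()
    if len(keep) < len(points):
        warnings.warn("duplicate consecutive annotation points collapsed", stacklevel=3)
    return points[keep]

MIN_BOUNDARY_SAMPLES = 8


def interpolate_boundary(ann: PointAnnotation, samples_per_segment: int = 8) -> VesselBoundary:
    """Closed periodic cubic spline through ordered boundary points.

    The curve passes through every annotated point exactly and is
    resampled uniformly in the knot parameter; the sample count is a
    multiple of the knot count so the knots are among the samples, and
    at least 8 points are returned.
    """
    if not ann.closed:
        raise ValidationError("interpolate_boundary requires a closed annotation")
    if samples_per_segment < 1:
        raise ValidationError("samples_per_segment must be >= 1")
    points = _dedupe_consecutive(ann.points, closed=True)
    k = len(points)
    if k < 3:
        raise ValidationError("a closed boundary needs >= 3 distinct points")
    # periodic spline: close the knot sequence
    knots = np.vstack([points, points[:1]])
    t = np.arange(k + 1, dtype=np.float64)
    spline_r = CubicSpline(t, knots[:, 0], bc_type="periodic")
    spline_c = CubicSpline(t, knots[:, 1], bc_type="periodic")
    per_seg = max(samples_per_segment, int(np.ceil(MIN_BOUNDARY_SAMPLES / k)))
    ts = np.linspace(0.0, k, k * per_seg, endpoint=False)
    curve = np.column_stack([spline_r(ts), spline_c(ts)])
    return VesselBoundary(curve=curve, source="manual")


def interpolate_curve(ann: PointAnnotation, samples_per_segment: int = 8) -> np.ndarray:
    """Natural cubic spline through ordered open-curve points.

    With exactly two points this is the straight segment between them.
    Returns an (n, 2) polyline passing through all knots.
    """
    if ann.closed:
        raise ValidationError("interpolate_curve requires an open annotation")
    if samples_per_segment < 1:
        raise ValidationError("samples_per_segment must be >= 1")
    points = _dedupe_consecutive(ann.points, closed=False)
    k = len(points)
    if k < 2:
        raise ValidationError("an open curve needs >= 2 distinct points")
    t = np.arange(k, dtype=np.float64)
    ts = np.linspace(0.0, k - 1, (k - 1) * samples_per_segment + 1)
    if k == 2:
        frac = ts[:, None]  # straight segment
        return points[0] + frac * (points[1] - points[0])
    spline_r = CubicSpline(t, points[:, 0], bc_type="natural")
    spline_c = CubicSpline(t, points[:, 1], bc_type="natural")
    return np.column_stack([spline_r(ts), spline_c(ts)])


# ---------------------------------------------------------------------------
# Semi-automatic CAM-vessel boundary: active contour from a rough mask
# ---------------------------------------------------------------------------

def _initial_contour_from_mask(mask: np.ndarray, n_points: int) -> np.ndarray:
    """Outer contour of the largest connected component, resampled."""
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValidationError("ROI mask is empty")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    component = labels == largest
    contours = measure.find_contours(component.astype(float), 0.5)
    if not contours:
        raise ValidationError("ROI mask component is too small to contour")
    contour = max(contours, key=lambda c: len(c))
    return _resample_closed(contour, n_points)


def _resample_closed(curve: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed curve to n points, uniform in arc length."""
    closed = curve
    if not np.allclose(closed[0], closed[-1]):
        closed = np.vstack([closed, closed[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValidationError("degenerate contour of zero length")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    rows = np.interp(targets, s, closed[:, 0])
    cols = np.interp(targets, s, closed[:, 1])
    return np.column_stack([rows, cols])


_SNAKE_CHUNK_ITERS = 25


def snake_segment(
    angio_display: np.ndarray,
    roi: RoiMask,
    params: Optional[SnakeParams] = None,
) -> VesselBoundary:
    """Evolve a snake from a rough ROI mask onto the vessel boundary.

    The initial contour is the outer contour of the ROI's largest
    connected component.  It minimizes internal energy (elasticity
    ``alpha``, rigidity ``beta``) plus an edge external energy computed
    from the Gaussian-smoothed (``sigma_px``) display image.  Iteration
    stops when the mean point displacement per iteration drops below
    ``tol`` pixels, or at ``max_iter``; the latter case is reported as
    ``metadata["converged"] = False`` rather than an error.
    """
    params = params or SnakeParams()
    image = np.asarray(angio_display, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError("snake input image must be 2-D")
    if roi.shape != image.shape:
        raise ValidationError(
            f"ROI shape {roi.shape} does not match image shape {image.shape}"
        )
    smoothed = gaussian(image, sigma=params.sigma_px, preserve_range=True)
    snake = _initial_contour_from_mask(roi.mask, params.n_points)

    converged = False
    iters_done = 0
    while iters_done < params.max_iter:
        step = min(_SNAKE_CHUNK_ITERS, params.max_iter - iters_done)
        new = active_contour(
            smoothed,
            snake,
            alpha=params.alpha,
            beta=params.beta,
            w_line=params.w_line,
            w_edge=params.w_edge,
            gamma=params.gamma,
            max_num_iter=step,
            convergence=0.0,  # chunk runs to completion; we test displacement
            boundary_condition="periodic",
        )
        mean_move = float(np.linalg.norm(new - snake, axis=1).mean()) / step
        snake = new
        iters_done += step
        if mean_move < params.tol:
            converged = True
            break

    return VesselBoundary(
        curve=snake,
        source="snake",
        metadata={"converged": converged, "iterations": iters_done},
    )


# ---------------------------------------------------------------------------
# Semi-automatic microvessels: skeleton centerlines from a rough mask
# ---------------------------------------------------------------------------

_NBR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
DEFAULT_PRUNE_PX = 5


def _neighbors(skel: np.ndarray, r: int, c: int) -> List[Tuple[int, int]]:
    m, n = skel.shape
    out = []
    for dr, dc in _NBR_OFFSETS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < m and 0 <= cc < n and skel[rr, cc]:
            out.append((rr, cc))
    return out


def _degree_map(skel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import convolve

    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    return convolve(skel.astype(np.uint8), kernel, mode="constant") * skel


def _prune_spurs(skel: np.ndarray, prune_px: float) -> np.ndarray:
    """Iteratively remove endpoint-to-junction paths shorter than prune_px."""
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        degree = _degree_map(skel)
        endpoints = np.argwhere((degree == 1) & skel)
        for r0, c0 in endpoints:
            if not skel[r0, c0]:
                continue
            path = [(int(r0), int(c0))]
            length = 0.0
            prev = None
            while True:
                r, c = path[-1]
                nbrs = [p for p in _neighbors(skel, r, c) if p != prev]
                if len(nbrs) != 1:
                    break  # reached a junction (or another endpoint/isolated px)
                nxt = nbrs[0]
                if degree[nxt] >= 3:
                    # spur terminates at a junction: eligible for pruning
                    if length + np.hypot(nxt[0] - r, nxt[1] - c) < prune_px:
                        for pr, pc in path:
                            skel[pr, pc] = False
                        changed = True
                    break
                length += np.hypot(nxt[0] - r, nxt[1] - c)
                prev = (r, c)
                path.append(nxt)
                if length >= prune_px:
                    break
    return skel


def _remove_redundant_corners(skel: np.ndarray) -> np.ndarray:
    """Drop degree-2 pixels whose two neighbors touch each other.

    Thinning can leave staircase 'triangles' (three mutually adjacent
    skeleton pixels); the corner pixel is redundant — removing it keeps
    the skeleton connected — but it inflates neighbor counts and fakes
    junctions, so it is peeled off before junction classification.
    """
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        degree = _degree_map(skel)
        for r, c in map(tuple, np.argwhere((degree == 2) & skel)):
            nbrs = _neighbors(skel, r, c)
            if len(nbrs) == 2 and max(
                abs(nbrs[0][0] - nbrs[1][0]), abs(nbrs[0][1] - nbrs[1][1])
            ) == 1:
                skel[r, c] = False
                changed = True
                degree = _degree_map(skel)
    return skel


def _junction_clusters(skel: np.ndarray) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Label junction pixels (>= 3 skeleton neighbors), merging adjacent ones."""
    degree = _degree_map(skel)
    junction_px = (degree >= 3) & skel
    labels = measure.label(junction_px, connectivity=2)
    centers = [
        tuple(np.mean(np.argwhere(labels == lab), axis=0))
        for lab in range(1, labels.max() + 1)
    ]
    return labels, centers


def skeletonize_mask(mask: RoiMask, prune_px: float = DEFAULT_PRUNE_PX) -> CenterlineSet:
    """Skeletonize a rough vessel-area mask into centerline polylines.

    The mask is thinned to a one-pixel-wide 8-connected skeleton; spurs
    (endpoint-to-junction paths) shorter than ``prune_px`` are removed;
    the remaining skeleton is split into polylines at junction pixels
    (skeleton pixels with >= 3 skeleton neighbors, adjacent junction
    pixels merged into one node).  Objects thinner than 2 px that
    skeletonize to a single pixel yield no curve.
    """
    if prune_px < 0:
        raise ValidationError("prune_px must be >= 0")
    skel = morphology.skeletonize(mask.mask)
    skel = _remove_redundant_corners(skel)
    if prune_px > 0:
        skel = _prune_spurs(skel, prune_px)
        # pruning can strand thick pixel clusters where a spur attached;
        # re-thinning plus corner cleanup restores a minimal skeleton
        skel = morphology.skeletonize(skel)
        skel = _remove_redundant_corners(skel)
    junction_labels, junction_centers = _junction_clusters(skel)
    is_junction = junction_labels > 0

    visited = np.zeros_like(skel, dtype=bool)
    curves: List[np.ndarray] = []

    def trace(start: Tuple[int, int], first: Tuple[int, int]) -> List[Tuple[int, int]]:
        """Walk edge pixels from `first` (adjacent to `start`) until a
        junction or endpoint, marking edge pixels visited."""
        path = [start, first]
        visited[first] = True
        while True:
            r, c = path[-1]
            if is_junction[r, c]:
                break
            nbrs = [
                p for p in _neighbors(skel, r, c)
                if p != path[-2] and (is_junction[p] or not visited[p])
            ]
            # prefer a non-junction continuation; junctions close the edge
            cont = [p for p in nbrs if not is_junction[p]]
            if cont:
                nxt = cont[0]
                visited[nxt] = True
            elif nbrs:
                nxt = nbrs[0]
            else:
                break
            path.append(nxt)
            if is_junction[nxt]:
                break
        return path

    # edges incident to junctions
    for r, c in map(tuple, np.argwhere(is_junction & skel)):
        for nbr in _neighbors(skel, r, c):
            if not is_junction[nbr] and not visited[nbr]:
                path = trace((r, c), nbr)
                if len(path) >= 2:
                    curves.append(np.asarray(path, dtype=np.float64))

    # open chains and isolated cycles with no junction
    degree = _degree_map(skel)
    for r, c in map(tuple, np.argwhere(skel & ~visited & ~is_junction)):
        if visited[r, c]:
            continue
        if degree[r, c] == 1:  # endpoint of an open chain
            visited[r, c] = True
            nbrs = [p for p in _neighbors(skel, r, c) if not visited[p]]
            if not nbrs:
                continue  # isolated pixel: no curve (small-object rule)
            path = trace((r, c), nbrs[0])
            if len(path) >= 2:
                curves.append(np.asarray(path, dtype=np.float64))
    for r, c in map(tuple, np.argwhere(skel & ~visited & ~is_junction)):
        if visited[r, c] or degree[r, c] != 2:
            continue  # leftover isolated pixels (degree 0)
        visited[r, c] = True
        nbrs = [p for p in _neighbors(skel, r, c) if not visited[p]]
        if nbrs:  # isolated cycle: break it at (r, c)
            path = trace((r, c), nbrs[0])
            if len(path) >= 2:
                curves.append(np.asarray(path, dtype=np.float64))

    return CenterlineSet(curves=curves, source="skeleton", junctions=junction_centers)
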