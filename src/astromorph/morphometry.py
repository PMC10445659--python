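"""Per-cell shape morphometry.

Measures the full-outline (FO) and convex-hull (CVH) parameter set used to
characterise projected astrocyte shapes: area, perimeter, fitted-ellipse axes,
circularity, roundness, solidity, the maximum Feret (caliper) diameter, the
geometric hull centroid, the intensity-weighted centre of mass, and the
fraction of the outline covered by a binarised marker channel (e.g. GFAP).

All pixel quantities are converted to physical units through the isotropic
XY pixel size (μm/px).  Conventions:

* FO area is the pixel count of the outline mask (holes excluded).
* Perimeter is the length of the smoothed sub-pixel boundary contour
  (marching squares at level 0.5, vertices averaged over a 3-point window to
  remove the staircase bias), summed over the outer boundary and any hole
  boundaries.  This stays within ~3% on digitised disks, ellipses and thin
  bars alike, where raw chain-code tracing overestimates a circle by ~5%
  and Crofton underestimates 2-3 px wide processes by ~6%.
* The convex hull is taken over the *corners* of boundary pixels, so a
  W x H pixel rectangle has hull side lengths W and H and Feret diameter
  sqrt(W^2 + H^2), matching how shapes are measured from traced outlines.
* Solidity is the ratio of FO pixel count to the pixel count of the
  rasterised hull (``skimage.morphology.convex_hull_image``), so
  ``fo_solidity == fo_area / cvh_area`` holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon
from skimage.measure import find_contours
from skimage.morphology import convex_hull_image

__all__ = [
    "ShapeMetrics",
    "SomaDisplacement",
    "boundary_corner_points",
    "convex_hull_vertices",
    "feret_diameter",
    "fit_ellipse",
    "shape_metrics",
    "soma_displacement",
]


@dataclass(frozen=True)
class ShapeMetrics:
    """The per-cell shape parameter set (lengths μm, areas μm², ratios unitless)."""

    fo_area: float
    fo_perimeter: float
    fo_major_axis: float
    fo_minor_axis: float
    fo_circularity: float
    fo_feret_diameter: float
    fo_roundness: float
    fo_solidity: float
    cvh_area: float
    cvh_perimeter: float
    cvh_feret_diameter: float
    cvh_centroid: tuple[float, float]
    fo_center_of_mass: tuple[float, float]
    centroid_com_distance: float
    marker_pct: float


def perimeter_smooth_contour(mask: np.ndarray, window: int = 3) -> float:
    """Boundary length (px) from smoothed sub-pixel contours.

    Marching-squares contours at level 0.5 are smoothed with a circular
    ``window``-point moving average before summing segment lengths; the
    smoothing turns pixel staircases into straight diagonals, removing the
    systematic overestimate of zigzag tracing.  Hole boundaries contribute.
    """
    mask = np.asarray(mask, bool)
    total = 0.0
    for c in find_contours(np.pad(mask, 1).astype(float), 0.5):
        pts = c[:-1]  # closed contour: last vertex repeats the first
        n = len(pts)
        if n < 3:
            continue
        if n <= window:
            closed = np.vstack([pts, pts[:1]])
            total += float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))
            continue
        kernel = np.ones(window) / window
        sm = np.empty_like(pts)
        half = window // 2
        for d in range(2):
            ext = np.r_[pts[-half:, d], pts[:, d], pts[:half, d]]
            sm[:, d] = np.convolve(ext, kernel, mode="valid")
        closed = np.vstack([sm, sm[:1]])
        total += float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))
    return total


@dataclass(frozen=True)
class SomaDisplacement:
    """Distance between the soma position and the convex-hull centroid (μm)."""

    soma_centroid: tuple[float, float]
    cvh_centroid: tuple[float, float]
    distance: float


def boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner points (x, y) of the boundary pixels of ``mask``.

    Each foreground pixel (i, j) spans the unit square with corners at
    (j ± 0.5, i ± 0.5).  Only boundary pixels contribute (interior corners
    cannot be hull vertices), which keeps the point set small.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    ii, jj = np.nonzero(boundary)
    corners = np.empty((ii.size * 4, 2), float)
    for k, (dy, dx) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        corners[k::4, 0] = jj + dx
        corners[k::4, 1] = ii + dy
    return np.unique(corners, axis=0)


def convex_hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices of an (N, 2) point set, counter-clockwise order."""
    points = np.asarray(points, float)
    if len(points) < 3:
        return points
    hull = ConvexHull(points)
    return points[hull.vertices]


def _rotating_calipers_max(hull: np.ndarray) -> tuple[float, int, int]:
    """Maximum caliper distance over CCW hull vertices via antipodal pairs."""
    n = len(hull)
    if n == 1:
        return 0.0, 0, 0
    if n == 2:
        return float(np.hypot(*(hull[1] - hull[0]))), 0, 1

    def area2(a, b, c):
        u, v = b - a, c - a
        return abs(float(u[0] * v[1] - u[1] * v[0]))

    best, bi, bj = 0.0, 0, 0
    j = 1
    for i in range(n):
        ni = (i + 1) % n
        # advance the caliper to the vertex farthest from edge (i, i+1)
        while area2(hull[i], hull[ni], hull[(j + 1) % n]) > area2(
            hull[i], hull[ni], hull[j]
        ):
            j = (j + 1) % n
        for a, b in ((i, j), (ni, j), (i, (j + 1) % n), (ni, (j + 1) % n)):
            d = float(np.hypot(*(hull[a] - hull[b])))
            if d > best:
                best, bi, bj = d, a, b
    return best, bi, bj


def feret_diameter(
    outline_or_mask, pixel_size: float = 1.0
) -> tuple[float, float, float]:
    """Maximum and minimum Feret diameter and the angle of the maximum.

    Accepts a boolean mask, an (N, 2) point array, or a
    :class:`~astromorph.segmentation.CellOutline`.  Returns
    ``(max_feret, min_feret, angle_deg)`` with lengths in μm.  The maximum is
    found by rotating calipers over the convex hull; the minimum is the
    smallest projection width over hull edge orientations.
    """
    points = _as_points(outline_or_mask)
    if len(points) < 2:
        d = float(np.hypot(pixel_size, pixel_size))
        return d, d, 0.0
    hull = convex_hull_vertices(points)
    dmax, i, j = _rotating_calipers_max(hull)
    vx, vy = hull[j] - hull[i]
    angle = float(np.degrees(np.arctan2(-vy, vx)) % 180.0)

    if len(hull) < 3:
        dmin = 0.0
    else:
        dmin = np.inf
        for e in range(len(hull)):
            edge = hull[(e + 1) % len(hull)] - hull[e]
            norm = np.hypot(*edge)
            if norm == 0:
                continue
            n_vec = np.array([-edge[1], edge[0]]) / norm
            proj = (hull - hull[e]) @ n_vec
            dmin = min(dmin, float(proj.max() - proj.min()))
    return dmax * pixel_size, dmin * pixel_size, angle


def _as_points(outline_or_mask) -> np.ndarray:
    if hasattr(outline_or_mask, "mask"):
        return boundary_corner_points(outline_or_mask.mask)
    arr = np.asarray(outline_or_mask)
    if arr.dtype == bool or arr.ndim == 2 and set(np.unique(arr)) <= {0, 1}:
        if arr.ndim == 2 and arr.shape[1] != 2:
            return boundary_corner_points(arr.astype(bool))
    return arr.astype(float)


def fit_ellipse(mask: np.ndarray, pixel_size: float = 1.0) -> tuple[float, float, float]:
    """Moment-matched ellipse: full major/minor axis (μm) and orientation (deg).

    The ellipse shares the region's second central moments and is rescaled so
    that its area equals the region's pixel area, mirroring the standard
    "fit ellipse" measurement.
    """
    mask = np.asarray(mask, bool)
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        raise ValueError("zero-area outline")
    x = jj - jj.mean()
    y = ii - ii.mean()
    # collinearity is judged on point moments, before the pixel-extent term
    pxx, pyy, pxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    p_common = np.sqrt((pxx - pyy) ** 2 + 4 * pxy**2)
    if (pxx + pyy - p_common) / 2.0 <= 1e-12:
        warnings.warn("collinear region: minor axis is zero", stacklevel=2)
        theta = 0.5 * np.arctan2(2 * pxy, pxx - pyy)
        major = 4.0 * np.sqrt(max((pxx + pyy + p_common) / 2.0, 0.0))
        return float(major * pixel_size), 0.0, float(np.degrees(-theta) % 180.0)
    # 1/12 term: each pixel is a unit square, not a point sample
    mxx = pxx + 1.0 / 12.0
    myy = pyy + 1.0 / 12.0
    mxy = pxy
    common = np.sqrt((mxx - myy) ** 2 + 4 * mxy**2)
    l1 = (mxx + myy + common) / 2.0
    l2 = (mxx + myy - common) / 2.0
    major = 4.0 * np.sqrt(max(l1, 0.0))
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    # rescale so ellipse area == pixel area
    scale = np.sqrt(4.0 * ii.size / (np.pi * major * minor))
    major *= scale
    minor *= scale
    theta = 0.5 * np.arctan2(2 * mxy, mxx - myy)
    angle = float(np.degrees(-theta) % 180.0)
    return float(major * pixel_size), float(minor * pixel_size), angle


def shape_metrics(
    outline,
    intensity_image: np.ndarray | None = None,
    marker_mask: np.ndarray | None = None,
    pixel_size: float | None = None,
) -> ShapeMetrics:
    """Measure the full FO/CVH parameter set of one cell outline.

    Parameters
    ----------
    outline
        A :class:`~astromorph.segmentation.CellOutline` or a boolean mask
        (in which case ``pixel_size`` must be given).
    intensity_image
        Optional 2D image (same shape as the mask) for the intensity-weighted
        centre of mass; defaults to the unweighted mask centroid.
    marker_mask
        Optional binary marker channel (e.g. locally-thresholded GFAP); the
        marker percentage is measured inside the outline mask.
    """
    if hasattr(outline, "mask"):
        mask = np.asarray(outline.mask, bool)
        px = outline.pixel_size if pixel_size is None else pixel_size
    else:
        mask = np.asarray(outline, bool)
        px = pixel_size
    if px is None:
        raise ValueError("pixel_size required when outline is a bare mask")
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("zero-area outline")

    area = n_px * px**2
    perim = perimeter_smooth_contour(mask) * px
    circularity = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 1.0

    major, minor, _ = fit_ellipse(mask, px)
    roundness = min(1.0, 4.0 * area / (np.pi * major**2)) if major > 0 else 1.0

    chull = convex_hull_image(mask)
    cvh_n = int(chull.sum())
    solidity = n_px / cvh_n
    cvh_area = cvh_n * px**2

    corners = boundary_corner_points(mask)
    hull_pts = convex_hull_vertices(corners)
    hull_poly = Polygon(hull_pts)
    cvh_perimeter = hull_poly.exterior.length * px
    fo_feret, _, _ = feret_diameter(corners, px)
    cvh_centroid = (hull_poly.centroid.x * px, hull_poly.centroid.y * px)

    ii, jj = np.nonzero(mask)
    if intensity_image is not None:
        w = np.asarray(intensity_image, float)[ii, jj]
        if w.sum() <= 0:
            w = np.ones_like(w)
        com = (float(np.average(jj, weights=w)) * px, float(np.average(ii, weights=w)) * px)
    else:
        com = (float(jj.mean()) * px, float(ii.mean()) * px)
    dist = float(np.hypot(com[0] - cvh_centroid[0], com[1] - cvh_centroid[1]))

    if marker_mask is not None:
        marker_pct = 100.0 * float(np.asarray(marker_mask, bool)[ii, jj].sum()) / n_px
    else:
        marker_pct = float("nan")

    return ShapeMetrics(
        fo_area=float(area),
        fo_perimeter=perim,
        fo_major_axis=major,
        fo_minor_axis=minor,
        fo_circularity=float(circularity),
        fo_feret_diameter=fo_feret,
        fo_roundness=float(roundness),
        fo_solidity=float(solidity),
        cvh_area=float(cvh_area),
        cvh_perimeter=float(cvh_perimeter),
        cvh_feret_diameter=fo_feret,
        cvh_centroid=cvh_centroid,
        fo_center_of_mass=com,
        centroid_com_distance=dist,
        marker_pct=marker_pct,
    )


def soma_displacement(
    outline, soma_centroid_um: tuple[float, float], pixel_size: float | None = None
) -> SomaDisplacement:
    """Euclidean distance (μm) from the soma to the convex-hull centroid.

    The soma position is taken from the soma-marker channel (or ground truth)
    in μm image coordinates.
    """
    if hasattr(outline, "mask"):
        mask = np.asarray(outline.mask, bool)
        px = outline.pixel_size if pixel_size is None else pixel_size
    else:
        mask = np.asarray(outline, bool)
        px = pixel_size
    sx, sy = soma_centroid_um
    h, w = mask.shape
    if not (0 <= sx <= w * px and 0 <= sy <= h * px):
        raise ValueError("soma centroid outside image")
    hull_pts = convex_hull_vertices(boundary_corner_points(mask))
    c = Polygon(hull_pts).centroid
    cx, cy = c.x * px, c.y * px
    return SomaDisplacement(
        soma_centroid=(float(sx), float(sy)),
        cvh_centroid=(float(cx), float(cy)),
        distance=float(np.hypot(sx - cx, sy - cy)),
    )
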