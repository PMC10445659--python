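"""Cell-outline extraction from multi-channel Z-stacks.

Reproduces the semi-automated outline workflow used for membrane-labelled
astrocytes: a standard-deviation Z-projection of the membrane channel is
auto-thresholded and binarised, connected particles above a minimum area
(default 3 μm²) are extracted together with their interior holes, and a
selected subset of particle/hole regions is combined with XOR into the final
complex cell outline.  Filamentous marker channels (GFAP) are binarised with
the Phansalkar local adaptive threshold (default radius 15 px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import (
    threshold_isodata,
    threshold_li,
    threshold_mean,
    threshold_otsu,
    threshold_triangle,
)
from skimage.measure import find_contours

__all__ = [
    "ProjectedImage",
    "Region",
    "CellOutline",
    "project_std",
    "threshold_global",
    "threshold_phansalkar",
    "extract_particles",
    "compose_outline",
    "select_regions_at",
    "outline_to_geojson",
]

_GLOBAL_METHODS = {
    "otsu": threshold_otsu,
    "isodata": threshold_isodata,
    "li": threshold_li,
    "mean": threshold_mean,
    "triangle": threshold_triangle,
}


@dataclass(frozen=True)
class ProjectedImage:
    """2D projection of one channel of a Z-stack, with provenance."""

    data: np.ndarray
    pixel_size: float
    channel: int | None = None
    method: str = "std"


@dataclass(frozen=True)
class Region:
    """One particle (or interior hole) found by connected-component analysis.

    ``mask`` is full-frame; for foreground particles it is hole-filled so
    that XOR with the particle's hole regions reproduces the complex outline.
    """

    label: int
    mask: np.ndarray
    area_px: int
    is_hole: bool
    parent: int | None = None


@dataclass(frozen=True)
class CellOutline:
    """Planar cell region: pixel mask, outer boundary polygon and holes.

    Boundary polygons are sub-pixel contours in (x, y) pixel coordinates
    (0-based, y-down).
    """

    mask: np.ndarray
    pixel_size: float
    boundary: np.ndarray = field(repr=False, default=None)
    holes: tuple[np.ndarray, ...] = field(repr=False, default=())

    @staticmethod
    def from_mask(mask: np.ndarray, pixel_size: float) -> "CellOutline":
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask")
        # outer boundaries are the contours of the hole-filled mask; hole
        # boundaries are the contours of the filled-minus-original residue
        filled = ndi.binary_fill_holes(mask)
        outers = [
            c[:, ::-1] - 1.0 for c in find_contours(np.pad(filled, 1).astype(float), 0.5)
        ]
        hole_region = filled & ~mask
        holes = [
            c[:, ::-1] - 1.0
            for c in find_contours(np.pad(hole_region, 1).astype(float), 0.5)
        ]
        outers.sort(key=_poly_area, reverse=True)
        return CellOutline(
            mask=mask, pixel_size=pixel_size, boundary=outers[0], holes=tuple(holes)
        )


def _poly_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def project_std(stack: np.ndarray, channel: int | None = None, pixel_size: float = 1.0) -> ProjectedImage:
    """Standard-deviation Z-projection (sample SD, ddof=1) of one channel.

    ``stack`` is (Z, Y, X) or (Z, C, Y, X) with ``channel`` selecting C.
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 4:
        if channel is None:
            raise ValueError("channel required for a multi-channel stack")
        stack = stack[:, channel]
    if stack.ndim != 3:
        raise ValueError("expected a (Z, Y, X) or (Z, C, Y, X) stack")
    if stack.shape[0] < 2:
        raise ValueError("projection requires >=2 planes")
    return ProjectedImage(
        data=stack.std(axis=0, ddof=1), pixel_size=pixel_size, channel=channel
    )


def threshold_global(image, method: str = "otsu") -> np.ndarray:
    """Auto-threshold and binarise a projected image (foreground above t)."""
    data = image.data if isinstance(image, ProjectedImage) else np.asarray(image, float)
    if np.ptp(data) == 0:
        raise ValueError("degenerate histogram: constant image")
    try:
        fn = _GLOBAL_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}") from None
    return data > fn(data)


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def threshold_phansalkar(
    image,
    radius: int = 15,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Phansalkar local adaptive threshold for low-contrast filament channels.

    Intensities are min-max normalised to [0, 1]; a pixel is foreground iff
    its value exceeds ``t = m * (1 + p*exp(-q*m) + k*(s/r - 1))`` where m and
    s are the mean and SD over the circular window of the given radius,
    with symmetric reflection at the borders.
    """
    data = image.data if isinstance(image, ProjectedImage) else np.asarray(image, float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(data.shape):
        raise ValueError("radius larger than image")
    lo, hi = data.min(), data.max()
    norm = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    foot = _disk_footprint(radius)
    n = foot.sum()
    m = ndi.correlate(norm, foot / n, mode="reflect")
    m2 = ndi.correlate(norm * norm, foot / n, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    t = m * (1.0 + p * np.exp(-q * m) + k * (s / r - 1.0))
    return norm > t


def extract_particles(
    mask: np.ndarray, pixel_size: float, min_area_um2: float = 3.0
) -> list[Region]:
    """Connected particles (8-connected) with area >= min_area, plus holes.

    Foreground components are returned hole-filled; each interior hole
    (4-connected background component not touching the border) is returned as
    its own region flagged ``is_hole`` with ``parent`` set to the enclosing
    particle's label.  Area bounds apply to particles only; holes of any size
    are reported so that the outline composition can reproduce them.
    """
    mask = np.asarray(mask, bool)
    min_px = min_area_um2 / pixel_size**2
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    regions: list[Region] = []
    filled_by_label: dict[int, np.ndarray] = {}
    for lbl in range(1, n + 1):
        comp = labels == lbl
        filled = ndi.binary_fill_holes(comp)
        area = int(filled.sum())
        if area < min_px:
            continue
        filled_by_label[lbl] = filled
        regions.append(Region(label=lbl, mask=filled, area_px=area, is_hole=False))

    # interior holes: 4-connected background components fully enclosed
    bg_labels, n_bg = ndi.label(~mask, structure=ndi.generate_binary_structure(2, 1))
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_bg = set(np.unique(bg_labels[border])) - {0}
    next_label = n + 1
    for hb in range(1, n_bg + 1):
        if hb in border_bg:
            continue
        hole = bg_labels == hb
        parent = None
        for lbl, filled in filled_by_label.items():
            if filled[hole].all():
                parent = lbl
                break
        regions.append(
            Region(
                label=next_label,
                mask=hole,
                area_px=int(hole.sum()),
                is_hole=True,
                parent=parent,
            )
        )
        next_label += 1
    return regions


def select_regions_at(regions: list[Region], seed_xy: tuple[float, float]) -> list[int]:
    """Automated stand-in for the interactive region picking step.

    Selects the particle containing the seed point together with all holes it
    encloses; returns their labels for :func:`compose_outline`.
    """
    j, i = int(round(seed_xy[0])), int(round(seed_xy[1]))
    chosen = None
    for reg in regions:
        if not reg.is_hole and 0 <= i < reg.mask.shape[0] and 0 <= j < reg.mask.shape[1]:
            if reg.mask[i, j]:
                chosen = reg
                break
    if chosen is None:
        return []
    ids = [chosen.label]
    ids += [r.label for r in regions if r.is_hole and chosen.mask[r.mask].all()]
    return ids


def compose_outline(
    regions: list[Region], selected_ids: list[int], pixel_size: float | None = None
) -> CellOutline:
    """XOR-compose selected particle/hole regions into the complex outline.

    The pixel mask is the symmetric difference of the selected region masks
    (order-independent); the outer boundary and hole polygons are extracted
    from the result.
    """
    by_label = {r.label: r for r in regions}
    missing = [i for i in selected_ids if i not in by_label]
    if missing:
        raise KeyError(f"unknown region ids: {missing}")
    if not selected_ids:
        raise ValueError("no regions selected")
    if not any(not by_label[i].is_hole for i in selected_ids):
        raise ValueError("at least one non-hole region must be selected")
    mask = np.zeros_like(by_label[selected_ids[0]].mask, bool)
    for i in selected_ids:
        mask ^= by_label[i].mask
    if not mask.any():
        raise ValueError("selection yields an empty mask")
    px = pixel_size if pixel_size is not None else 1.0
    return CellOutline.from_mask(mask, px)


def outline_to_geojson(outline: CellOutline) -> dict:
    """Outline as a GeoJSON-style polygon record (pixel coords, y-down)."""
    return {
        "type": "Polygon",
        "coordinates": [outline.boundary.tolist()]
        + [h.tolist() for h in outline.holes],
        "properties": {"pixel_size_um": outline.pixel_size},
    }
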