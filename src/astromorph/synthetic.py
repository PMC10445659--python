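"""Synthetic flat-mount retina scenes with exact ground truth.

Generates the inputs every downstream stage consumes — a 5-channel Z-stack
(membrane / GFAP-like / vessel / soma / axon), a motif annotation table and a
cell-position table — together with a :class:`GroundTruth` record of the true
geometry, so that segmentation, morphometry, vessel-contact analysis and the
association statistics can all be tested against known answers without the
original imaging data.

Construction is vector-first: vessels are random planar trees of buffered
centerlines (each branching event spawns one *new* unique vessel while the
parent *continues*, so a tree with ``b`` branch events has ``1 + b`` unique
vessels); astrocytes are deformed core polygons with buffered process
polylines, planted structural motifs (bead, sail, tube, bristle, pad,
end-foot, hole) at the length scales seen in membrane-labelled cells
(bristles at most ~5 μm, the smallest 0.7-2.5 μm), and interior holes.
Ground-truth shape metrics come from the exact polygon geometry, independent
of the raster measurement code under test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import shapely
import shapely.affinity
import shapely.wkt
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import substring, unary_union

from .vasculature import VesselNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SceneParams",
    "CellSpec",
    "MotifTruth",
    "CellTruth",
    "VesselTruth",
    "GroundTruth",
    "generate_vessel_network",
    "generate_astrocyte",
    "render_flatmount",
    "generate_annotation_table",
    "network_from_truth",
    "rasterize",
    "write_stack",
    "sample_contact_cohort",
    "sample_annotation_cohort",
    "sample_eccentricity_cohort",
    "sample_morphology_populations",
]

CHANNELS = ("membrane", "gfap", "vessel", "soma", "axon")

#: Default per-motif probabilities that an instance contacts each structure.
#: Non-vascular motif values follow the observed conditional probabilities
#: p(structure | motif) for sails, beads, pads and bristles.
DEFAULT_MOTIF_CONTACT_PROBS: dict[str, dict[str, float]] = {
    "sail": {"axon": 0.65, "soma": 0.41, "astrocyte": 0.06},
    "bead": {"axon": 0.76, "soma": 0.22, "astrocyte": 0.03},
    "pad": {"axon": 0.43, "soma": 0.43, "astrocyte": 0.20},
    "bristle": {"axon": 0.41, "soma": 0.34, "astrocyte": 0.20},
    "tube": {"axon": 0.10, "soma": 0.0, "astrocyte": 0.0},
    "end-foot": {"axon": 0.10, "soma": 0.0, "astrocyte": 0.0},
    "hole": {"axon": 0.30, "soma": 0.0, "astrocyte": 0.0},
}


@dataclass(frozen=True)
class CellSpec:
    """Recipe for one synthetic astrocyte."""

    area_um2: float = 600.0
    n_processes: int = 4
    motifs: tuple[str, ...] = ()
    soma_offset_um: float | None = None
    connection_class: str = "non-enveloping"
    process_length_um: tuple[float, float] = (8.0, 18.0)
    process_width_um: tuple[float, float] = (1.2, 2.4)
    bristle_length_um: tuple[float, float] = (2.0, 5.0)
    sail_extent_um: tuple[float, float] = (6.0, 12.0)
    hole_radius_um: tuple[float, float] = (1.5, 3.5)
    pad_radius_um: tuple[float, float] = (1.5, 2.5)
    core_fraction: float = 0.75
    deform: float = 0.12
    closing_um: float = 0.3


@dataclass(frozen=True)
class SceneParams:
    """Study conditions of one synthetic flat-mount scene.

    Defaults emulate the acquisition and population regime the pipeline is
    designed for: 0.3 μm XY sampling and 0.3 μm Z-steps, a planted GFAP-like
    coverage fraction of 21.1% of each cell's area, and a vascular tree with
    a handful of branching events crossing the field.
    """

    shape: tuple[int, int, int] = (6, 640, 640)  # (Z, Y, X)
    pixel_size_um: float = 0.3
    z_step_um: float = 0.3
    vessel_root_radius_um: float = 4.0
    n_vessel_branches: int = 3
    vessel_radius_decay: float = 0.8
    n_cells: int = 9
    cell_area_range_um2: tuple[float, float] = (300.0, 900.0)
    motif_pool: tuple[str, ...] = ("bead", "sail", "bristle", "pad", "end-foot", "hole")
    motifs_per_cell: tuple[int, int] = (1, 3)
    class_fractions: tuple[float, float, float] = (0.08, 0.07, 0.85)
    gfap_fraction: float = 0.211
    soma_offset_um: float | None = None
    noise_sigma: float = 0.05
    n_background_axons: int = 5
    eye: str = "left"
    rim_distance_um: float = 1600.0
    phi0_deg: float = 22.0
    overlap_pairs: int = 0
    max_overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel size and z-step must be positive")


@dataclass
class MotifTruth:
    motif: str
    polygon: Polygon
    contacts: dict[str, bool] = field(default_factory=dict)


@dataclass
class CellTruth:
    """Generator-side truth for one cell (all geometry in scene μm)."""

    cell_id: int
    polygon: Polygon
    area_um2: float
    perimeter_um: float
    feret_um: float
    solidity: float
    hull_centroid_um: tuple[float, float]
    soma_um: tuple[float, float]
    soma_offset_um: float
    motifs: list[MotifTruth]
    connection_class: str
    gfap_fraction: float
    n_unique_contacts: int = 0
    contacted_vessel_ids: list[int] = field(default_factory=list)
    latitude: float = 0.0
    longitude: float = 0.0
    retina_xy_um: tuple[float, float] = (0.0, 0.0)


@dataclass
class VesselTruth:
    """True centerline geometry: one entry per unique vessel id."""

    segments: list[tuple[np.ndarray, float, int]]  # (points μm, radius μm, id)
    branch_points: list[tuple[float, float]]
    n_branches: int

    @property
    def n_unique(self) -> int:
        return len({vid for _, _, vid in self.segments})


@dataclass
class GroundTruth:
    params: SceneParams
    vessels: VesselTruth
    cells: list[CellTruth]
    overlaps: list[tuple[int, int]] = field(default_factory=list)


# --------------------------------------------------------------------------
# rasterization

def rasterize(geom, shape_yx: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean mask of pixels whose centers (j*px, i*px) fall inside ``geom``."""
    mask = np.zeros(shape_yx, bool)
    if geom.is_empty:
        return mask
    minx, miny, maxx, maxy = geom.bounds
    j0 = max(int(np.floor(minx / pixel_size)) - 1, 0)
    j1 = min(int(np.ceil(maxx / pixel_size)) + 2, shape_yx[1])
    i0 = max(int(np.floor(miny / pixel_size)) - 1, 0)
    i1 = min(int(np.ceil(maxy / pixel_size)) + 2, shape_yx[0])
    if j1 <= j0 or i1 <= i0:
        return mask
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    inside = shapely.contains_xy(geom, jj.ravel() * pixel_size, ii.ravel() * pixel_size)
    mask[i0:i1, j0:j1] = inside.reshape(i1 - i0, j1 - j0)
    return mask


def polygon_metrics(poly: Polygon) -> dict[str, float]:
    """Exact shape metrics of a polygon: the generator-side oracle."""
    hull = poly.convex_hull
    pts = np.asarray(hull.exterior.coords)[:-1]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    feret = float(np.sqrt(d2.max()))
    perimeter = poly.exterior.length + sum(r.length for r in poly.interiors)
    return {
        "area_um2": float(poly.area),
        "perimeter_um": float(perimeter),
        "feret_um": feret,
        "solidity": float(poly.area / hull.area),
    }


# --------------------------------------------------------------------------
# vessels

def _grow_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    bounds: tuple[float, float],
    step: float = 5.0,
    jitter_deg: float = 6.0,
    max_length: float | None = None,
) -> np.ndarray:
    W, H = bounds
    pts = [start.astype(float)]
    length = 0.0
    while True:
        heading += np.radians(rng.uniform(-jitter_deg, jitter_deg))
        nxt = pts[-1] + step * np.array([np.cos(heading), np.sin(heading)])
        if not (0 <= nxt[0] <= W and 0 <= nxt[1] <= H):
            break
        pts.append(nxt)
        length += step
        if max_length is not None and length >= max_length:
            break
    return np.array(pts)


def generate_vessel_network(
    params: SceneParams, seed: int | None = None
) -> tuple[VesselTruth, np.ndarray]:
    """Random planar vessel tree and its rasterised tube mask.

    Each branching event keeps the parent vessel *continuing* through the
    branch point and starts exactly one *new* unique vessel, so the tree has
    ``1 + n_vessel_branches`` unique vessels by construction.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    px = params.pixel_size_um
    _, ny, nx_ = params.shape
    W, H = nx_ * px, ny * px
    if params.vessel_root_radius_um / px < 1.0:
        raise ValueError("unresolvable vessel: root radius below 1 px")

    root = _grow_polyline(
        rng, np.array([0.0, rng.uniform(0.35, 0.65) * H]), rng.uniform(-0.2, 0.2), (W, H)
    )
    segments: list[tuple[np.ndarray, float, int]] = [
        (root, params.vessel_root_radius_um, 0)
    ]
    branch_points: list[tuple[float, float]] = []
    next_id = 1
    while next_id <= params.n_vessel_branches:
        # pick a branch point on an existing vessel, away from other branches,
        # and grow a new daughter that stays clear of every other tube
        placed = False
        for _ in range(200):
            si = int(rng.integers(len(segments)))
            pts, radius, _vid = segments[si]
            if len(pts) < 8:
                continue
            bi = int(rng.integers(2, len(pts) - 2))
            bp = pts[bi]
            if branch_points and min(
                np.hypot(bp[0] - q[0], bp[1] - q[1]) for q in branch_points
            ) < 15.0:
                continue
            local = pts[min(bi + 1, len(pts) - 1)] - pts[bi - 1]
            heading = np.arctan2(local[1], local[0]) + rng.choice([-1, 1]) * np.radians(
                rng.uniform(35, 60)
            )
            new_radius = max(radius * params.vessel_radius_decay, px)
            branch = _grow_polyline(
                rng, bp.copy(), heading, (W, H), max_length=rng.uniform(50, 120)
            )
            # truncate where the daughter would collide with another tube;
            # the parent counts too, once the daughter has left the junction
            others = [
                (LineString(p2), r2, i2 == si)
                for i2, (p2, r2, _) in enumerate(segments)
                if len(p2) >= 2
            ]
            keep = len(branch)
            for pi in range(3, len(branch)):
                p = Point(branch[pi])
                from_bp = np.hypot(branch[pi][0] - bp[0], branch[pi][1] - bp[1])
                for line, r2, is_parent in others:
                    clearance = new_radius + r2 + 1.5
                    if is_parent and from_bp <= clearance + 4.0:
                        continue
                    if line.distance(p) < clearance:
                        keep = pi
                        break
                if keep == pi:
                    break
            branch = branch[:keep]
            if len(branch) < 5:
                continue
            segments.append((branch, new_radius, next_id))
            branch_points.append((float(bp[0]), float(bp[1])))
            placed = True
            break
        if not placed:  # pragma: no cover - field saturated with vessels
            logger.warning("could not place vessel branch %d", next_id)
            break
        next_id += 1

    tubes = unary_union(
        [LineString(pts).buffer(r, quad_segs=8) for pts, r, _ in segments]
    )
    mask = rasterize(tubes, (ny, nx_), px)
    truth = VesselTruth(
        segments=segments, branch_points=branch_points, n_branches=len(branch_points)
    )
    return truth, mask


def network_from_truth(truth: VesselTruth, pixel_size: float) -> VesselNetwork:
    """Exact centerline graph built from generator truth (no raster step).

    Nodes are (y, x) pixel-unit tuples so the graph is interchangeable with
    the skeleton-derived one; branch points are shared nodes.
    """
    g = nx.Graph()

    def node_key(p):
        return (round(p[1] / pixel_size, 3), round(p[0] / pixel_size, 3))

    for pts, radius, vid in truth.segments:
        keys = [node_key(p) for p in pts]
        for key, p in zip(keys, pts):
            g.add_node(
                key, x=key[1], y=key[0], radius_um=float(radius)
            )
        for a, b in zip(keys[:-1], keys[1:]):
            if a != b:
                g.add_edge(a, b)
    # branch polylines start exactly at a parent vertex, so branch points are
    # shared nodes by construction
    branch = [n for n in g if g.degree(n) >= 3]
    return VesselNetwork(graph=g, pixel_size=pixel_size, branch_points=branch)


def vessel_union_by_id(truth: VesselTruth) -> dict[int, shapely.Geometry]:
    """Buffered tube geometry per unique vessel id (truth-side contacts)."""
    out: dict[int, list] = {}
    for pts, r, vid in truth.segments:
        out.setdefault(vid, []).append(LineString(pts).buffer(r, quad_segs=8))
    return {vid: unary_union(geoms) for vid, geoms in out.items()}


# --------------------------------------------------------------------------
# cells

def _deformed_core(
    rng: np.random.Generator, r0: float, center: np.ndarray, deform: float = 0.12
) -> Polygon:
    th = np.linspace(0, 2 * np.pi, 96, endpoint=False)
    r = r0 * (
        1.0
        + sum(
            rng.uniform(0.0, deform) * np.cos(k * th + rng.uniform(0, 2 * np.pi))
            for k in range(2, 6)
        )
    )
    return Polygon(np.c_[center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def _boundary_point(poly: Polygon, angle: float, center: np.ndarray) -> np.ndarray:
    ray = LineString(
        [center, center + 10000.0 * np.array([np.cos(angle), np.sin(angle)])]
    )
    hit = poly.exterior.intersection(ray)
    if hit.is_empty:
        return np.asarray(poly.exterior.coords[0])
    if hit.geom_type == "Point":
        return np.array([hit.x, hit.y])
    pts = [g for g in getattr(hit, "geoms", [hit]) if g.geom_type == "Point"]
    if not pts:
        return np.asarray(poly.exterior.coords[0])
    d = [np.hypot(p.x - center[0], p.y - center[1]) for p in pts]
    p = pts[int(np.argmax(d))]
    return np.array([p.x, p.y])


def _nearest_vessel_segment(
    point: np.ndarray, vessels: VesselTruth | None
) -> tuple[np.ndarray, float, int, float] | None:
    if vessels is None or not vessels.segments:
        return None
    best = None
    for pts, r, vid in vessels.segments:
        line = LineString(pts)
        d = line.distance(Point(point))
        if best is None or d < best[3]:
            best = (pts, r, vid, d)
    return best


def generate_astrocyte(
    spec: CellSpec,
    center_um: tuple[float, float],
    vessels: VesselTruth | None = None,
    seed: int | np.random.Generator = 0,
    cell_id: int = 0,
) -> CellTruth:
    """Build one astrocyte polygon with planted motifs and exact truth.

    Raises ``ValueError`` naming the missing structure if a vessel-requiring
    motif (tube, end-foot) or connection class is requested without vessels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = np.asarray(center_um, float)
    needs_vessel = (
        spec.connection_class in ("enveloping", "mural")
        or "tube" in spec.motifs
        or "end-foot" in spec.motifs
    )
    if needs_vessel and (vessels is None or not vessels.segments):
        missing = "tube" if "tube" in spec.motifs else (
            "end-foot" if "end-foot" in spec.motifs else spec.connection_class
        )
        raise ValueError(f"motif/class {missing!r} requires a vessel within reach")

    parts: list = []
    holes: list[Polygon] = []
    motif_truths: list[MotifTruth] = []

    if spec.connection_class == "enveloping":
        poly, motif_truths = _enveloping_cell(spec, center, vessels, rng)
    elif spec.connection_class == "mural":
        poly, motif_truths = _mural_cell(spec, center, vessels, rng)
    else:
        r0 = float(np.sqrt(spec.core_fraction * spec.area_um2 / np.pi))
        core = _deformed_core(rng, r0, center, spec.deform)
        parts.append(core)
        for _ in range(spec.n_processes):
            ang = rng.uniform(0, 2 * np.pi)
            start = _boundary_point(core, ang, center)
            length = rng.uniform(*spec.process_length_um)
            line = _grow_polyline(
                rng, start, ang, (1e9, 1e9), step=3.0, jitter_deg=15.0, max_length=length
            )
            if len(line) >= 2:
                parts.append(
                    LineString(line).buffer(rng.uniform(*spec.process_width_um) / 2)
                )
        for motif in spec.motifs:
            geom = _plant_motif(motif, spec, core, center, vessels, rng, holes, parts)
            if geom is not None:
                motif_truths.append(MotifTruth(motif=motif, polygon=geom))
        poly = unary_union(parts).buffer(0)
        # sub-resolution crevices where parts meet tangentially are not
        # resolvable at the imaging scale; close them at ~1 px
        poly = poly.buffer(spec.closing_um, quad_segs=8).buffer(
            -spec.closing_um, quad_segs=8
        )
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
        for h in holes:
            h_in = h.intersection(poly.buffer(-0.8))
            if h_in.is_empty or h_in.geom_type != "Polygon":
                continue
            candidate = poly.difference(h_in)
            if candidate.geom_type == "Polygon":
                poly = candidate
                motif_truths.append(MotifTruth(motif="hole", polygon=h_in))

    metrics = polygon_metrics(poly)
    hull_c = poly.convex_hull.centroid
    soma, actual_offset = _place_soma(poly, (hull_c.x, hull_c.y), spec.soma_offset_um, rng)
    return CellTruth(
        cell_id=cell_id,
        polygon=poly,
        area_um2=metrics["area_um2"],
        perimeter_um=metrics["perimeter_um"],
        feret_um=metrics["feret_um"],
        solidity=metrics["solidity"],
        hull_centroid_um=(float(hull_c.x), float(hull_c.y)),
        soma_um=soma,
        soma_offset_um=actual_offset,
        motifs=motif_truths,
        connection_class=spec.connection_class,
        gfap_fraction=float("nan"),
    )


def _plant_motif(motif, spec, core, center, vessels, rng, holes, parts):
    ang = rng.uniform(0, 2 * np.pi)
    anchor = _boundary_point(core, ang, center)
    direction = np.array([np.cos(ang), np.sin(ang)])
    if motif == "bristle":
        # short fine projection <= ~5 um; the smallest 0.7-2.5 um
        length = (
            rng.uniform(0.7, 2.5) if rng.random() < 0.3 else rng.uniform(*spec.bristle_length_um)
        )
        tip = anchor + length * direction
        geom = LineString([anchor, tip]).buffer(0.45, quad_segs=6)
        parts.append(geom)
        return geom
    if motif == "bead":
        stem = LineString([anchor, anchor + 4.0 * direction]).buffer(0.3)
        bead = Point(anchor + 4.0 * direction).buffer(rng.uniform(0.8, 1.5), quad_segs=8)
        parts += [stem, bead]
        return bead
    if motif == "sail":
        extent = rng.uniform(*spec.sail_extent_um)
        half = rng.uniform(0.4, 0.7) * extent
        perp = np.array([-direction[1], direction[0]])
        tipa = anchor + extent * direction + half * perp
        tipb = anchor + extent * direction - half * perp
        geom = Polygon([anchor - 2.0 * perp, anchor + 2.0 * perp, tipa, tipb]).buffer(0)
        if geom.geom_type != "Polygon" or geom.is_empty:
            geom = Polygon([anchor, tipa, tipb])
        parts.append(geom)
        return geom
    if motif == "pad":
        # rounded flat ending away from vessels
        if vessels is not None and vessels.segments:
            near = _nearest_vessel_segment(anchor, vessels)
            vdir = near[0][min(len(near[0]) - 1, 1)] - anchor
            if np.dot(direction, vdir) > 0:
                direction = -direction
                anchor = _boundary_point(core, ang + np.pi, center)
        stem_len = rng.uniform(5.0, 10.0)
        tip = anchor + stem_len * direction
        stem = LineString([anchor, tip]).buffer(0.6)
        pad = Point(tip).buffer(rng.uniform(*spec.pad_radius_um), quad_segs=8)
        parts += [stem, pad]
        return pad
    if motif == "end-foot":
        near = _nearest_vessel_segment(center, vessels)
        pts, r, vid, _d = near
        line = LineString(pts)
        q = line.interpolate(line.project(Point(center)))
        to_v = np.array([q.x, q.y]) - center
        dist = np.hypot(*to_v)
        u = to_v / dist if dist > 0 else direction
        pad_r = rng.uniform(*spec.pad_radius_um)
        # pad center sits so the pad overlaps the vessel surface slightly
        pad_c = np.array([q.x, q.y]) - (r + pad_r - 0.4) * u
        start = _boundary_point(core, np.arctan2(u[1], u[0]), center)
        stem = LineString([start, pad_c]).buffer(0.6)
        foot = Point(pad_c).buffer(pad_r, quad_segs=8)
        parts += [stem, foot]
        return foot
    if motif == "tube":
        near = _nearest_vessel_segment(center, vessels)
        pts, r, vid, _d = near
        line = LineString(pts)
        s = line.project(Point(center))
        seg_len = rng.uniform(8.0, 15.0)
        lo, hi = max(0.0, s - seg_len / 2), min(line.length, s + seg_len / 2)
        sub = substring(line, lo, hi)
        # projected tube: a solid band over the vessel footprint
        ring = sub.buffer(r + 1.5, quad_segs=8)
        q = sub.interpolate(0.5, normalized=True)
        start = _boundary_point(core, np.arctan2(q.y - center[1], q.x - center[0]), center)
        stem = LineString([start, (q.x, q.y)]).buffer(0.8)
        parts += [stem, ring]
        return ring
    if motif == "hole":
        r_h = rng.uniform(*spec.hole_radius_um)
        r0 = float(np.sqrt(spec.core_fraction * spec.area_um2 / np.pi))
        off = rng.uniform(0.2, 0.55) * r0
        hole_c = center + off * direction
        holes.append(Point(hole_c).buffer(r_h, quad_segs=8))
        return None  # recorded after punching succeeds
    raise ValueError(f"unknown motif {motif!r}")


def _enveloping_cell(spec, center, vessels, rng):
    # an enveloping sleeve projects en face to a solid band covering the
    # vessel footprint: membrane above and below the vessel overlap in Z
    pts, r, vid, _ = _nearest_vessel_segment(center, vessels)
    line = LineString(pts)
    s = line.project(Point(center))
    wall = 1.8
    caps = np.pi * (r + wall) ** 2
    length = max((spec.area_um2 - caps) / (2 * (r + wall)), 5.0)
    lo, hi = max(0.0, s - length / 2), min(line.length, s + length / 2)
    sub = substring(line, lo, hi)
    band = sub.buffer(r + wall, quad_segs=8)
    motifs = [MotifTruth(motif="tube", polygon=band)]
    return band, motifs


def _mural_cell(spec, center, vessels, rng):
    pts, r, vid, _ = _nearest_vessel_segment(center, vessels)
    line = LineString(pts)
    s = line.project(Point(center))
    wall = 2.2
    # one-sided band hugging the vessel: partial wrap, as at junctions
    length = max(spec.area_um2 / (r + wall), 5.0)
    lo, hi = max(0.0, s - length / 2), min(line.length, s + length / 2)
    sub = substring(line, lo, hi)
    side = float(rng.choice([-1.0, 1.0]))
    wedge = sub.buffer(side * (r + wall), single_sided=True, quad_segs=8).buffer(0)
    if wedge.geom_type == "MultiPolygon":
        wedge = max(wedge.geoms, key=lambda p: p.area)
    return wedge, []


def _place_soma(poly, hull_centroid, offset, rng):
    cx, cy = hull_centroid
    if offset is None:
        r_eq = np.sqrt(poly.area / np.pi)
        offset = float(rng.uniform(0.1, 0.5) * r_eq)
    target = float(offset)
    angles = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    while target > 0.25:
        order = rng.permutation(len(angles))
        for k in order:
            p = Point(cx + target * np.cos(angles[k]), cy + target * np.sin(angles[k]))
            if poly.contains(p):
                return (float(p.x), float(p.y)), target
        target *= 0.85
    p = poly.representative_point()
    return (float(p.x), float(p.y)), float(np.hypot(p.x - cx, p.y - cy))


# --------------------------------------------------------------------------
# scene rendering

def _gfap_subset(cell_mask: np.ndarray, fraction: float) -> np.ndarray:
    """Filamentous subset of a cell mask covering ~``fraction`` of its area."""
    from scipy import ndimage as ndi
    from skimage.morphology import skeletonize

    n_target = int(round(fraction * cell_mask.sum()))
    if n_target <= 0:
        return np.zeros_like(cell_mask)
    skel = skeletonize(cell_mask)
    if not skel.any():
        return cell_mask.copy()
    dist = ndi.distance_transform_edt(~skel)
    ii, jj = np.nonzero(cell_mask)
    order = np.lexsort((jj, ii, dist[ii, jj]))
    sel = order[:n_target]
    out = np.zeros_like(cell_mask)
    out[ii[sel], jj[sel]] = True
    return out


def render_flatmount(params: SceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render a complete scene: (Z, C, Y, X) float32 stack plus ground truth.

    Channel order: membrane, GFAP-like, vessel, soma, axon.  Z-planes carry a
    deterministic intensity profile (so a standard-deviation projection is
    informative) and, with ``noise_sigma == 0``, the membrane channel support
    equals the union of the true cell masks exactly.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx_ = params.shape
    px = params.pixel_size_um
    W, H = nx_ * px, ny * px

    vessel_truth, vessel_mask = generate_vessel_network(params, seed=int(rng.integers(2**31)))

    # --- plan cells on a jittered grid
    n = params.n_cells
    cols = max(1, int(np.ceil(np.sqrt(n * W / H))))
    rows = int(np.ceil(n / cols))
    tile_w, tile_h = W / cols, H / rows
    class_labels = ["enveloping", "mural", "non-enveloping"]
    cls = rng.choice(class_labels, size=n, p=list(params.class_fractions))
    field_box = box(1.5 * px, 1.5 * px, W - 1.5 * px, H - 1.5 * px)

    cells: list[CellTruth] = []
    placed_union = None
    for k in range(n):
        r_, c_ = divmod(k, cols)
        cx = (c_ + 0.5) * tile_w + rng.uniform(-0.08, 0.08) * tile_w
        cy = (r_ + 0.5) * tile_h + rng.uniform(-0.08, 0.08) * tile_h
        n_motifs = int(rng.integers(params.motifs_per_cell[0], params.motifs_per_cell[1] + 1))
        motifs = tuple(rng.choice(params.motif_pool, size=n_motifs, replace=True))
        connection = str(cls[k])
        if connection == "non-enveloping" and "end-foot" not in motifs and "tube" not in motifs:
            # every astrocyte contacts at least one vessel; non-enveloping
            # cells do so through an end-foot rather than by wrapping
            motifs = motifs + ("end-foot",)
        spec = CellSpec(
            area_um2=float(rng.uniform(*params.cell_area_range_um2)),
            n_processes=int(rng.integers(3, 7)),
            motifs=motifs,
            soma_offset_um=params.soma_offset_um,
            connection_class=connection,
        )
        truth = None
        for attempt in range(24):
            spread = min(0.05 + 0.04 * attempt, 0.45)
            center = np.array(
                [
                    cx + rng.uniform(-spread, spread) * tile_w,
                    cy + rng.uniform(-spread, spread) * tile_h,
                ]
            )
            near = _nearest_vessel_segment(center, vessel_truth)
            line = LineString(near[0])
            s_proj = line.project(Point(center))
            if spec.connection_class in ("enveloping", "mural"):
                # slide along the vessel on retries to dodge neighbours
                shift = (attempt + 1) // 2 * 18.0 * (-1 if attempt % 2 else 1)
                q = line.interpolate(np.clip(s_proj + shift, 0.0, line.length))
                center = np.array([q.x, q.y])
            else:
                # keep the core body off the vessel: contact happens via the
                # end-foot process, as in non-enveloping cells
                q = line.interpolate(s_proj)
                r0 = np.sqrt(0.75 * spec.area_um2 / np.pi)
                to_cell = center - np.array([q.x, q.y])
                d = np.hypot(*to_cell)
                if d < r0 + 4.0:
                    u = to_cell / d if d > 0 else np.array([1.0, 0.0])
                    center = np.array([q.x, q.y]) + (r0 + 5.0) * u
            candidate = generate_astrocyte(
                spec, tuple(center), vessel_truth, seed=rng, cell_id=k
            )
            if (
                params.overlap_pairs == 0
                and placed_union is not None
                and candidate.polygon.distance(placed_union) < 3 * px
            ):
                continue
            truth = candidate
            break
        if truth is None:
            truth = candidate
            logger.warning("cell %d could not be placed without near-contact", k)
        clipped = truth.polygon.intersection(field_box)
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda p: p.area)
        if clipped.area < truth.polygon.area:
            m = polygon_metrics(clipped)
            hc = clipped.convex_hull.centroid
            soma, off = _place_soma(clipped, (hc.x, hc.y), truth.soma_offset_um, rng)
            truth = replace(
                truth,
                polygon=clipped,
                area_um2=m["area_um2"],
                perimeter_um=m["perimeter_um"],
                feret_um=m["feret_um"],
                solidity=m["solidity"],
                hull_centroid_um=(float(hc.x), float(hc.y)),
                soma_um=soma,
                soma_offset_um=off,
            )
        cells.append(truth)
        placed_union = (
            truth.polygon
            if placed_union is None
            else unary_union([placed_union, truth.polygon])
        )

    # planted overlapping pairs, e.g. for inclusion-filter tests
    for pair in range(params.overlap_pairs):
        if len(cells) < 2 * (pair + 1):
            break
        a = cells[2 * pair]
        b = cells[2 * pair + 1]
        dx = a.hull_centroid_um[0] - b.hull_centroid_um[0]
        dy = a.hull_centroid_um[1] - b.hull_centroid_um[1]
        moved = shapely.affinity.translate(
            b.polygon, xoff=dx * 0.82, yoff=dy * 0.82
        ).intersection(field_box)
        if moved.geom_type == "MultiPolygon":
            moved = max(moved.geoms, key=lambda p: p.area)
        m = polygon_metrics(moved)
        hc = moved.convex_hull.centroid
        soma, off = _place_soma(moved, (hc.x, hc.y), None, rng)
        cells[2 * pair + 1] = replace(
            b,
            polygon=moved,
            area_um2=m["area_um2"],
            perimeter_um=m["perimeter_um"],
            feret_um=m["feret_um"],
            solidity=m["solidity"],
            hull_centroid_um=(float(hc.x), float(hc.y)),
            soma_um=soma,
            soma_offset_um=off,
        )

    overlaps = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            inter = cells[i].polygon.intersection(cells[j].polygon)
            if not inter.is_empty and inter.area > 0:
                frac = inter.area / min(cells[i].polygon.area, cells[j].polygon.area)
                if frac > params.max_overlap_fraction:
                    logger.warning(
                        "cells %d and %d overlap (fraction %.3f)", i, j, frac
                    )
                overlaps.append((i, j))

    # --- truth-side vessel contacts and retina coordinates
    tubes = vessel_union_by_id(vessel_truth)
    tol = 1.0 * px
    for cell in cells:
        ids = sorted(
            vid for vid, tube in tubes.items() if cell.polygon.distance(tube) <= tol
        )
        cell.contacted_vessel_ids = ids
        cell.n_unique_contacts = len(ids)
        r = params.rim_distance_um * np.sqrt(rng.uniform(0.02, 0.98))
        theta = rng.uniform(0, 2 * np.pi)
        cell.retina_xy_um = (float(r * np.cos(theta)), float(r * np.sin(theta)))
        cell.latitude = float((r / params.rim_distance_um - 1.0) * np.pi / 2)
        cell.longitude = float(theta)  # dorsal axis at pi/2 in planar frame

    # --- rasterize channels
    membrane = np.zeros((ny, nx_), bool)
    gfap = np.zeros((ny, nx_), bool)
    soma_img = np.zeros((ny, nx_), float)
    axon_geoms = []
    yy, xx = np.mgrid[:ny, :nx_]
    for cell in cells:
        cmask = rasterize(cell.polygon, (ny, nx_), px)
        membrane |= cmask
        g = _gfap_subset(cmask, params.gfap_fraction)
        cell.gfap_fraction = float(g.sum() / max(cmask.sum(), 1))
        gfap |= g
        sx, sy = cell.soma_um
        sig = 2.0 / px
        blob = np.exp(-(((xx - sx / px) ** 2 + (yy - sy / px) ** 2) / (2 * sig**2)))
        soma_img = np.maximum(soma_img, np.where(blob > 0.01, blob, 0.0))
        # plant contacted structures for flagged motifs
        for mt in cell.motifs:
            probs = DEFAULT_MOTIF_CONTACT_PROBS.get(mt.motif, {})
            mt.contacts = {
                s: bool(rng.random() < probs.get(s, 0.0))
                for s in ("axon", "soma", "astrocyte")
            }
            c = mt.polygon.centroid
            if mt.contacts["axon"]:
                ang = rng.uniform(0, np.pi)
                d = np.array([np.cos(ang), np.sin(ang)])
                axon_geoms.append(
                    LineString([np.array([c.x, c.y]) - 40 * d, np.array([c.x, c.y]) + 40 * d]).buffer(0.6)
                )
            if mt.contacts["soma"]:
                axon_geoms.append(Point(c.x + 1.0, c.y).buffer(3.5))  # RGC soma blob
            if mt.contacts["astrocyte"]:
                ang = rng.uniform(0, 2 * np.pi)
                d = np.array([np.cos(ang), np.sin(ang)])
                neighbor = LineString(
                    [np.array([c.x, c.y]), np.array([c.x, c.y]) + 25 * d]
                ).buffer(0.8)
                gfap |= rasterize(neighbor, (ny, nx_), px)
    for _ in range(params.n_background_axons):
        y0 = rng.uniform(0, H)
        ang = rng.uniform(-0.3, 0.3)
        d = np.array([np.cos(ang), np.sin(ang)])
        axon_geoms.append(LineString([(-10, y0), np.array([-10, y0]) + (W + 20) * d]).buffer(0.7))
    axon_mask = rasterize(unary_union(axon_geoms), (ny, nx_), px) if axon_geoms else np.zeros((ny, nx_), bool)

    planes = np.stack(
        [
            membrane.astype(np.float32),
            gfap.astype(np.float32),
            vessel_mask.astype(np.float32),
            soma_img.astype(np.float32),
            axon_mask.astype(np.float32),
        ]
    )
    zprof = 0.55 + 0.45 * np.sin(np.pi * (np.arange(nz) + 0.5) / nz)
    phase = np.linspace(0.0, 0.3, len(CHANNELS))
    stack = np.empty((nz, len(CHANNELS), ny, nx_), np.float32)
    for z in range(nz):
        for c in range(len(CHANNELS)):
            stack[z, c] = planes[c] * np.float32(zprof[z] + phase[c] * (z % 2))
    if params.noise_sigma > 0:
        stack += rng.normal(0.0, params.noise_sigma, stack.shape).astype(np.float32)

    truth = GroundTruth(params=params, vessels=vessel_truth, cells=cells, overlaps=overlaps)
    return stack, truth


def generate_annotation_table(truth: GroundTruth) -> pd.DataFrame:
    """One row per planted motif instance with its contacted-structure flags."""
    rows = [
        {
            "cell_id": cell.cell_id,
            "motif": mt.motif,
            "axon": bool(mt.contacts.get("axon", False)),
            "soma": bool(mt.contacts.get("soma", False)),
            "astrocyte": bool(mt.contacts.get("astrocyte", False)),
        }
        for cell in truth.cells
        for mt in cell.motifs
    ]
    return pd.DataFrame(rows, columns=["cell_id", "motif", "axon", "soma", "astrocyte"])


def write_stack(path, stack: np.ndarray) -> None:
    """Write an ImageJ-compatible multi-page TIFF with ZCYX axes."""
    import tifffile

    tifffile.imwrite(path, stack, imagej=True, metadata={"axes": "ZCYX"})


def truth_to_json(truth: GroundTruth) -> str:
    """Serialise ground truth (polygons as WKT) to a JSON string."""

    def cell_dict(c: CellTruth) -> dict:
        return {
            "cell_id": c.cell_id,
            "polygon_wkt": c.polygon.wkt,
            "area_um2": c.area_um2,
            "perimeter_um": c.perimeter_um,
            "feret_um": c.feret_um,
            "solidity": c.solidity,
            "hull_centroid_um": list(c.hull_centroid_um),
            "soma_um": list(c.soma_um),
            "soma_offset_um": c.soma_offset_um,
            "connection_class": c.connection_class,
            "gfap_fraction": c.gfap_fraction,
            "n_unique_contacts": c.n_unique_contacts,
            "contacted_vessel_ids": list(c.contacted_vessel_ids),
            "latitude": c.latitude,
            "longitude": c.longitude,
            "retina_xy_um": list(c.retina_xy_um),
            "motifs": [
                {"motif": m.motif, "polygon_wkt": m.polygon.wkt, "contacts": m.contacts}
                for m in c.motifs
            ],
        }

    payload = {
        "pixel_size_um": truth.params.pixel_size_um,
        "z_step_um": truth.params.z_step_um,
        "seed": truth.params.seed,
        "n_unique_vessels": truth.vessels.n_unique,
        "n_branches": truth.vessels.n_branches,
        "vessel_segments": [
            {"points_um": pts.tolist(), "radius_um": r, "vessel_id": vid}
            for pts, r, vid in truth.vessels.segments
        ],
        "cells": [cell_dict(c) for c in truth.cells],
        "overlaps": [list(o) for o in truth.overlaps],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# statistical cohorts (no imaging): planted population regimes

def sample_contact_cohort(
    n_cells: int = 1045,
    mean_unique_contacts: float = 2.57,
    p_axon: float = 0.990,
    p_soma: float = 0.978,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort of per-cell contact records with every cell on >=1 vessel.

    Unique-contact counts are 1 + Poisson(mean - 1) so the planted mean is
    exact and the 100%-vessel-contact property holds by construction.
    """
    rng = np.random.default_rng(seed)
    counts = 1 + rng.poisson(mean_unique_contacts - 1.0, size=n_cells)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "n_unique_vessels": counts,
            "contacts_axon": rng.random(n_cells) < p_axon,
            "contacts_soma": rng.random(n_cells) < p_soma,
        }
    )


def sample_annotation_cohort(
    counts: dict[str, int] | None = None,
    probs: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif annotation table sampled at planted contact probabilities.

    Default instance counts per motif match the error magnitudes of the
    observed association table (sail 48, bead 89, pad 14, bristle 10).
    """
    rng = np.random.default_rng(seed)
    counts = counts or {"sail": 48, "bead": 89, "pad": 14, "bristle": 10}
    probs = probs or DEFAULT_MOTIF_CONTACT_PROBS
    rows = []
    cell = 0
    for motif, n in counts.items():
        pr = probs[motif]
        for _ in range(n):
            rows.append(
                {
                    "cell_id": cell,
                    "motif": motif,
                    "axon": bool(rng.random() < pr.get("axon", 0.0)),
                    "soma": bool(rng.random() < pr.get("soma", 0.0)),
                    "astrocyte": bool(rng.random() < pr.get("astrocyte", 0.0)),
                }
            )
            cell += 1
    return pd.DataFrame(rows, columns=["cell_id", "motif", "axon", "soma", "astrocyte"])


def sample_eccentricity_cohort(
    n: int = 500,
    peak_latitude: float = -np.pi / 4,
    peak_value: float = 2000.0,
    curvature: float = -1500.0,
    noise_sd: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells whose value peaks in the mid-retina (negative quadratic trend)."""
    rng = np.random.default_rng(seed)
    lat = rng.uniform(-np.pi / 2, 0.0, size=n)
    value = peak_value + curvature * (lat - peak_latitude) ** 2 + rng.normal(
        0, noise_sd, size=n
    )
    return pd.DataFrame({"latitude_rad": lat, "value": value})


def sample_morphology_populations(
    n: int = 300, n_populations: int = 3, separation: float = 6.0, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Well-separated synthetic morphology populations in the 20-feature space.

    Returns (feature matrix with the canonical columns, true population
    labels); used to exercise the embedding + density clustering stage.
    """
    from .stats import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    base = np.array(
        [900, 400, 60, 30, 0.3, 70, 0.4, 0.6, 1400, 140, 70, -0.8, np.pi, 21, 10, 15, 8, 6, 10, 2.5]
    )
    sd = np.abs(base) * 0.08 + 0.02
    labels = np.repeat(np.arange(n_populations), int(np.ceil(n / n_populations)))[:n]
    X = np.empty((n, len(base)))
    offsets = rng.normal(0, 1, size=(n_populations, len(base)))
    offsets = offsets / np.linalg.norm(offsets, axis=1, keepdims=True) * separation
    for i, lab in enumerate(labels):
        X[i] = base + sd * (offsets[lab] + rng.normal(0, 1, len(base)))
    return pd.DataFrame(X, columns=list(FEATURE_COLUMNS)), labels
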