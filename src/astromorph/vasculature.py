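"""Astrocyte-vessel relationships.

Skeletonises the vessel (IB4) channel into a centerline graph with per-node
radii, partitions the skeleton into *unique vessels* (each branching event
yields one continuing vessel and one new one), and measures per-cell
quantities: distance from the hull centroid to the nearest vessel, the set of
unique vessels contacted with their diameters, and the three-way connection
classification (enveloping / mural / non-enveloping).

The "continuing" branch at a bifurcation is operationalised as the pair of
incident segments whose tangents are most collinear (largest |cos θ|);
diameter similarity is available as an alternative pairing criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

logger = logging.getLogger(__name__)

__all__ = [
    "VesselNetwork",
    "VesselContact",
    "ConnectionClass",
    "skeletonize_vessels",
    "split_unique_vessels",
    "distance_to_nearest_vessel",
    "find_contacts",
    "classify_connection",
    "export_graphml",
]


@dataclass
class VesselNetwork:
    """Centerline graph of a vessel mask.

    Nodes are skeleton pixels ``(i, j)`` with attributes ``x``/``y`` (px),
    ``radius_um``; after :func:`split_unique_vessels` every edge carries a
    ``vessel_id`` and nodes carry the id of one incident vessel.
    """

    graph: nx.Graph
    pixel_size: float
    n_unique: int | None = None
    branch_points: list[tuple[int, int]] = field(default_factory=list)

    @property
    def node_positions(self) -> np.ndarray:
        return np.array(list(self.graph.nodes))


@dataclass(frozen=True)
class VesselContact:
    """Contact between one cell and one unique vessel."""

    cell_id: int | str
    vessel_id: int
    n_pixels: int
    d_min: float
    d_mean: float
    d_max: float


@dataclass(frozen=True)
class ConnectionClass:
    """Three-way vascular connection classification of one cell."""

    label: str  # enveloping | mural | non-enveloping
    wrap_deg: float
    on_vessel_fraction: float


def skeletonize_vessels(vessel_mask: np.ndarray, pixel_size: float) -> VesselNetwork:
    """Medial-axis centerline graph with distance-transform radii."""
    mask = np.asarray(vessel_mask, bool)
    if not mask.any():
        raise ValueError("empty vessel mask")
    skel = skeletonize(mask)
    if not skel.any():
        raise ValueError("vessel mask thinner than 1 px: skeleton empty")
    radius = ndi.distance_transform_edt(mask) * pixel_size
    g = nx.Graph()
    ii, jj = np.nonzero(skel)
    for i, j in zip(ii, jj):
        g.add_node((int(i), int(j)), x=int(j), y=int(i), radius_um=float(radius[i, j]))
    skel_set = set(zip(ii.tolist(), jj.tolist()))
    for i, j in skel_set:
        for di, dj in ((-1, 0), (0, -1)):
            if (i + di, j + dj) in skel_set:
                g.add_edge((i, j), (i + di, j + dj))
        # diagonal adjacency only where no orthogonal 2-step path exists,
        # otherwise every staircase corner becomes a spurious 3-cycle
        for di, dj in ((-1, -1), (-1, 1)):
            if (i + di, j + dj) in skel_set:
                if (i + di, j) in skel_set or (i, j + dj) in skel_set:
                    continue
                g.add_edge((i, j), (i + di, j + dj))
    _prune_spurs(g, radius, pixel_size)
    branch = [n for n in g if g.degree(n) >= 3]
    return VesselNetwork(graph=g, pixel_size=pixel_size, branch_points=branch)


def _prune_spurs(g: nx.Graph, radius_um: np.ndarray, pixel_size: float) -> None:
    """Remove terminal skeleton twigs shorter than the local vessel radius.

    Thinning rounded tube ends and junctions leaves short side twigs; each
    would otherwise register as a spurious branching event.  A leaf path is a
    genuine vessel end only if it is longer than the tube is wide there.
    """
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in g if g.degree(n) == 1]:
            path = [leaf]
            while g.degree(path[-1]) <= 2:
                nbrs = [m for m in g.neighbors(path[-1]) if m not in path]
                if not nbrs:
                    break
                path.append(nbrs[0])
            junction = path[-1]
            if g.degree(junction) < 3:
                continue  # isolated path, not a spur
            length_px = sum(
                np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(path[:-1], path[1:])
            )
            local_r_px = radius_um[junction] / pixel_size
            if length_px < local_r_px + 2.0:
                g.remove_nodes_from(path[:-1])
                changed = True


def _extract_segments(g: nx.Graph) -> list[list]:
    """Paths between special nodes (degree != 2), plus pure cycles."""
    special = {n for n in g if g.degree(n) != 2}
    visited: set[frozenset] = set()
    segments = []
    for s in special:
        for nb in g.neighbors(s):
            e = frozenset((s, nb))
            if e in visited:
                continue
            visited.add(e)
            path = [s, nb]
            while path[-1] not in special:
                nxt = [m for m in g.neighbors(path[-1]) if m != path[-2]]
                if not nxt:
                    break
                visited.add(frozenset((path[-1], nxt[0])))
                path.append(nxt[0])
            segments.append(path)
    # pure cycles (every node degree 2) have no special node to start from
    seen = {n for seg in segments for n in seg} | special
    for comp in nx.connected_components(g):
        if not comp & seen:
            start = next(iter(comp))
            cycle_nodes = list(nx.dfs_preorder_nodes(g.subgraph(comp), start))
            segments.append(cycle_nodes + [start])
    return segments


def _tangent(seg: list, end_node, pixel_size: float, reach: int = 6) -> np.ndarray:
    """Unit tangent of a segment pointing away from ``end_node``."""
    if seg[0] == end_node:
        pts = seg[: min(len(seg), reach)]
        v = np.array(pts[-1]) - np.array(pts[0])
    else:
        pts = seg[-min(len(seg), reach) :]
        v = np.array(pts[0]) - np.array(pts[-1])
    n = np.hypot(*v)
    return v / n if n > 0 else v


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def split_unique_vessels(
    network: VesselNetwork, criterion: str = "collinearity"
) -> VesselNetwork:
    """Partition the centerline graph into unique vessels.

    At each branch point the two incident segments that pair best under the
    chosen criterion ("collinearity": most collinear tangents;
    "diameter": most similar radii) merge into the continuing vessel; every
    unpaired segment starts a new unique vessel.  Cyclic components fall back
    to one vessel per inter-branch segment with a logged warning.
    """
    g = network.graph
    segments = _extract_segments(g)
    uf = _UnionFind(len(segments))

    cyclic_nodes: set = set()
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() >= sub.number_of_nodes():
            cyclic_nodes |= set(comp)
            logger.warning(
                "cyclic vessel component (%d nodes): each segment kept as its own vessel",
                len(comp),
            )

    # incident segments per special node
    incident: dict = {}
    for si, seg in enumerate(segments):
        for end in (seg[0], seg[-1]):
            incident.setdefault(end, []).append(si)

    for node, seg_ids in incident.items():
        if g.degree(node) < 3 or node in cyclic_nodes:
            continue
        scores = []
        for a in range(len(seg_ids)):
            for b in range(a + 1, len(seg_ids)):
                sa, sb = seg_ids[a], seg_ids[b]
                if criterion == "diameter":
                    ra = np.mean([g.nodes[n]["radius_um"] for n in segments[sa]])
                    rb = np.mean([g.nodes[n]["radius_um"] for n in segments[sb]])
                    score = -abs(ra - rb)
                else:
                    ta = _tangent(segments[sa], node, network.pixel_size)
                    tb = _tangent(segments[sb], node, network.pixel_size)
                    score = abs(float(ta @ tb))
                scores.append((score, sa, sb))
        scores.sort(key=lambda t: -t[0])
        used: set[int] = set()
        for score, sa, sb in scores:
            if sa in used or sb in used:
                continue
            uf.union(sa, sb)
            used |= {sa, sb}
            if g.degree(node) == 3:
                break  # one continuing pair; the third segment starts anew

    roots = sorted({uf.find(i) for i in range(len(segments))})
    vid_of_root = {r: k for k, r in enumerate(roots)}
    for si, seg in enumerate(segments):
        vid = vid_of_root[uf.find(si)]
        for a, b in zip(seg[:-1], seg[1:]):
            g.edges[a, b]["vessel_id"] = vid
        for n in seg:
            g.nodes[n].setdefault("vessel_id", vid)
    network.n_unique = len(roots)
    return network


def distance_to_nearest_vessel(
    point_um: tuple[float, float], vessel_mask: np.ndarray, pixel_size: float
) -> float:
    """Distance (μm) from a point to the nearest vessel pixel (0 on a vessel)."""
    mask = np.asarray(vessel_mask, bool)
    if not mask.any():
        raise ValueError("no vessels")
    h, w = mask.shape
    j = point_um[0] / pixel_size
    i = point_um[1] / pixel_size
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError("point outside image")
    dist = ndi.distance_transform_edt(~mask)
    ii, jj = int(round(i)), int(round(j))
    return float(dist[min(ii, h - 1), min(jj, w - 1)]) * pixel_size


def find_contacts(
    cell_mask: np.ndarray,
    network: VesselNetwork,
    vessel_mask: np.ndarray,
    tolerance_px: int = 1,
    cell_id: int | str = 0,
) -> list[VesselContact]:
    """Unique-vessel contacts of one cell.

    A contact exists where the cell mask dilated by ``tolerance_px``
    intersects the vessel mask; intersecting pixels are assigned to the
    unique vessel of the nearest centerline node, and only unique vessels are
    counted.  Diameters are 2x the node radius over the contacted nodes.
    """
    if network.n_unique is None:
        raise ValueError("unique-vessel partition not filled; run split_unique_vessels")
    cell = np.asarray(cell_mask, bool)
    vessels = np.asarray(vessel_mask, bool)
    dil = ndi.binary_dilation(cell, iterations=tolerance_px) if tolerance_px else cell
    inter = dil & vessels
    if not inter.any():
        return []
    nodes = list(network.graph.nodes)
    tree = cKDTree(np.array(nodes, float))
    pix = np.argwhere(inter)
    _, idx = tree.query(pix)
    contacted_nodes: dict[int, set[int]] = {}
    counts: dict[int, int] = {}
    for ni in idx:
        node = nodes[ni]
        vid = network.graph.nodes[node]["vessel_id"]
        contacted_nodes.setdefault(vid, set()).add(ni)
        counts[vid] = counts.get(vid, 0) + 1
    out = []
    for vid in sorted(contacted_nodes):
        ds = np.array(
            [
                2.0 * network.graph.nodes[nodes[ni]]["radius_um"]
                for ni in sorted(contacted_nodes[vid])
            ]
        )
        out.append(
            VesselContact(
                cell_id=cell_id,
                vessel_id=int(vid),
                n_pixels=int(counts[vid]),
                d_min=float(ds.min()),
                d_mean=float(ds.mean()),
                d_max=float(ds.max()),
            )
        )
    return out


def classify_connection(
    cell_mask: np.ndarray,
    network: VesselNetwork,
    vessel_mask: np.ndarray,
    tolerance_px: int = 1,
    wrap_envelope_deg: float = 300.0,
    wrap_mural_deg: float = 120.0,
    min_mass_fraction: float = 0.5,
    shell_um: float = 2.0,
    bin_deg: float = 10.0,
) -> ConnectionClass:
    """Classify a cell's vascular connection as enveloping, mural or non-enveloping.

    The on-vessel mass fraction is the fraction of cell pixels within
    ``shell_um`` of the vessel surface.  The wrap statistic is the median,
    over contacted centerline nodes, of the angular coverage (occupied
    ``bin_deg`` bins) of cell pixels within twice the local vessel radius.
    Enveloping: wrap >= ``wrap_envelope_deg`` and fraction >=
    ``min_mass_fraction``; mural: wrap >= ``wrap_mural_deg`` and the same
    fraction bound; otherwise non-enveloping.  The classification is total:
    cells touching no vessel are non-enveloping (with a warning).
    """
    cell = np.asarray(cell_mask, bool)
    vessels = np.asarray(vessel_mask, bool)
    px = network.pixel_size
    contacts = find_contacts(cell, network, vessels, tolerance_px)
    if not contacts:
        warnings.warn("cell contacts no vessel; classified non-enveloping", stacklevel=2)
        return ConnectionClass("non-enveloping", 0.0, 0.0)

    shell_px = max(1, int(round(shell_um / px)))
    near_vessel = ndi.binary_dilation(vessels, iterations=shell_px)
    frac = float((cell & near_vessel).sum()) / float(cell.sum())

    contacted = {c.vessel_id for c in contacts}
    cpix = np.argwhere(cell)
    tree = cKDTree(cpix.astype(float))
    wraps = []
    nbins = int(round(360.0 / bin_deg))
    for node, data in network.graph.nodes(data=True):
        if data["vessel_id"] not in contacted:
            continue
        r_px = max(data["radius_um"] / px, 1.0)
        # sample only cross-sections inside the contact footprint: the cell
        # must reach the vessel surface at this node, otherwise distant nodes
        # that glimpse a few cell pixels dilute the wrap statistic
        nearest, _ = tree.query(np.array(node, float))
        if nearest > r_px + tolerance_px + 1.0:
            continue
        idx = tree.query_ball_point(np.array(node, float), 2.0 * r_px)
        if not idx:
            continue
        rel = cpix[idx] - np.array(node)
        # only material outside the vessel surface counts as wrap: pixels over
        # the footprint itself are projection overlap, not wrapping
        norm = np.hypot(rel[:, 0], rel[:, 1])
        rel = rel[norm >= r_px - 0.5]
        if len(rel) == 0:
            continue
        ang = np.arctan2(rel[:, 0], rel[:, 1]) % (2 * np.pi)
        occupied = np.unique((ang / (2 * np.pi) * nbins).astype(int))
        wraps.append(len(occupied) * bin_deg)
    wrap = float(np.median(wraps)) if wraps else 0.0

    if wrap >= wrap_envelope_deg and frac >= min_mass_fraction:
        label = "enveloping"
    elif wrap >= wrap_mural_deg and frac >= min_mass_fraction:
        label = "mural"
    else:
        label = "non-enveloping"
    return ConnectionClass(label, wrap, frac)


def export_graphml(network: VesselNetwork, path) -> None:
    """Write the centerline graph as GraphML (x, y, radius_um, vessel_id)."""
    g = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        g.add_node(f"{node[0]}_{node[1]}", **{k: data[k] for k in data})
    for a, b, data in network.graph.edges(data=True):
        g.add_edge(f"{a[0]}_{a[1]}", f"{b[0]}_{b[1]}", **data)
    nx.write_graphml(g, path)
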