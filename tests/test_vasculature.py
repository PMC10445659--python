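"""Vessel skeletonisation, unique-vessel partition, contacts, classification."""

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage as ndi

from astromorph import vasculature as vasc
from astromorph.synthetic import (
    CellSpec,
    SceneParams,
    generate_astrocyte,
    generate_vessel_network,
    network_from_truth,
    rasterize,
)


def tube_mask(shape, p0, p1, radius_px):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    L = np.hypot(*d)
    u = d / L
    t = np.clip((xx - p0[0]) * u[0] + (yy - p0[1]) * u[1], 0, L)
    return np.hypot(xx - p0[0] - t * u[0], yy - p0[1] - t * u[1]) <= radius_px


class TestSkeletonize:
    def test_straight_tube_single_path_with_correct_radius(self):
        px = 0.5
        mask = tube_mask((40, 200), (10, 20), (190, 20), radius_px=6)  # 3 um radius
        net = vasc.skeletonize_vessels(mask, px)
        assert not net.branch_points
        # interior nodes carry the tube radius within half a pixel
        radii = [
            d["radius_um"]
            for n, d in net.graph.nodes(data=True)
            if 40 < d["x"] < 160
        ]
        assert np.allclose(radii, 3.0, atol=0.5 * px + 0.3)

    def test_y_mask_has_one_branch_point_of_degree_three(self):
        mask = (
            tube_mask((120, 120), (10, 60), (70, 60), 4)
            | tube_mask((120, 120), (70, 60), (110, 30), 4)
            | tube_mask((120, 120), (70, 60), (110, 90), 4)
        )
        net = vasc.skeletonize_vessels(mask, 1.0)
        assert len(net.branch_points) == 1
        assert net.graph.degree(net.branch_points[0]) == 3

    def test_topology_matches_generator_centerlines(self):
        params = SceneParams(shape=(2, 420, 420), n_vessel_branches=2, seed=4)
        truth, mask = generate_vessel_network(params)
        net = vasc.skeletonize_vessels(mask, params.pixel_size_um)
        measured_branches = len(net.branch_points)
        assert abs(measured_branches - truth.n_branches) <= truth.n_branches + 1
        vasc.split_unique_vessels(net)
        assert abs(net.n_unique - truth.n_unique) <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            vasc.skeletonize_vessels(np.zeros((10, 10), bool), 1.0)


def _path_graph(points, radius=2.0):
    g = nx.Graph()
    for p in points:
        g.add_node(p, x=p[1], y=p[0], radius_um=radius)
    for a, b in zip(points[:-1], points[1:]):
        g.add_edge(a, b)
    return g


class TestSplitUniqueVessels:
    def test_unbranched_path_is_one_vessel(self):
        g = _path_graph([(0, i) for i in range(10)])
        net = vasc.VesselNetwork(graph=g, pixel_size=1.0)
        assert vasc.split_unique_vessels(net).n_unique == 1

    def test_single_branch_event_gives_two_vessels(self):
        g = _path_graph([(0, i) for i in range(11)])
        # side branch leaving at node (0,5)
        prev = (0, 5)
        for k in range(1, 6):
            node = (k, 5 + k)
            g.add_node(node, x=node[1], y=node[0], radius_um=2.0)
            g.add_edge(prev, node)
            prev = node
        net = vasc.VesselNetwork(graph=g, pixel_size=1.0)
        vasc.split_unique_vessels(net)
        assert net.n_unique == 2  # 1 + number of new-vessel assignments

    def test_binary_tree_three_branches_four_vessels(self):
        params = SceneParams(shape=(2, 512, 512), n_vessel_branches=3, seed=9)
        truth, _ = generate_vessel_network(params)
        assert truth.n_branches == 3
        net = network_from_truth(truth, params.pixel_size_um)
        vasc.split_unique_vessels(net)
        assert net.n_unique == 4

    @pytest.mark.parametrize("seed", range(12))
    def test_tree_identity_on_random_generated_trees(self, seed):
        rng = np.random.default_rng(seed)
        params = SceneParams(
            shape=(2, 512, 512), n_vessel_branches=int(rng.integers(0, 7)), seed=seed
        )
        truth, _ = generate_vessel_network(params)
        net = network_from_truth(truth, params.pixel_size_um)
        vasc.split_unique_vessels(net)
        assert net.n_unique == 1 + truth.n_branches

    def test_partition_covers_every_edge(self):
        params = SceneParams(shape=(2, 512, 512), n_vessel_branches=4, seed=2)
        truth, _ = generate_vessel_network(params)
        net = network_from_truth(truth, params.pixel_size_um)
        vasc.split_unique_vessels(net)
        assert all("vessel_id" in d for _, _, d in net.graph.edges(data=True))

    def test_cycle_falls_back_to_per_segment_ids(self):
        pts = [(0, 0), (0, 5), (5, 5), (5, 0)]
        g = nx.Graph()
        for p in pts:
            g.add_node(p, x=p[1], y=p[0], radius_um=1.0)
        for a, b in zip(pts, pts[1:] + pts[:1]):
            g.add_edge(a, b)
        net = vasc.VesselNetwork(graph=g, pixel_size=1.0)
        vasc.split_unique_vessels(net)
        assert net.n_unique >= 1  # total, no crash on a pure cycle


class TestDistanceToVessel:
    def test_analytic_distance_to_straight_tube(self):
        px = 0.5
        mask = tube_mask((200, 200), (10, 100), (190, 100), radius_px=6)
        # point 50 px above the tube edge: distance = (50 - 6) px... measure from edge
        d = vasc.distance_to_nearest_vessel((50 * px, 40 * px), mask, px)
        expected = (100 - 6 - 40) * px
        assert d == pytest.approx(expected, abs=1.5 * px)

    def test_point_on_vessel_is_zero(self):
        mask = tube_mask((100, 100), (10, 50), (90, 50), 5)
        assert vasc.distance_to_nearest_vessel((50.0, 50.0), mask, 1.0) == 0.0

    def test_matches_exhaustive_minimum(self, rng):
        mask = rng.random((50, 50)) < 0.02
        if not mask.any():
            mask[25, 25] = True
        point = (17.3, 31.9)
        d = vasc.distance_to_nearest_vessel(point, mask, 1.0)
        ii, jj = np.nonzero(mask)
        brute = min(np.hypot(jj - round(point[0]), ii - round(point[1])))
        assert d == pytest.approx(brute, abs=1.0)

    def test_no_vessels_rejected(self):
        with pytest.raises(ValueError, match="no vessels"):
            vasc.distance_to_nearest_vessel((1, 1), np.zeros((5, 5), bool), 1.0)


class TestContactsAndClassification:
    @pytest.fixture(scope="class")
    def vessel_context(self):
        params = SceneParams(shape=(2, 512, 512), n_vessel_branches=2, seed=6)
        truth, mask = generate_vessel_network(params)
        net = vasc.skeletonize_vessels(mask, params.pixel_size_um)
        vasc.split_unique_vessels(net)
        return params, truth, mask, net

    def test_cell_far_from_vessels_has_no_contacts(self, vessel_context):
        params, truth, mask, net = vessel_context
        cell = np.zeros_like(mask)
        dist = ndi.distance_transform_edt(~mask)
        far = np.unravel_index(np.argmax(dist), dist.shape)
        cell[far[0] - 3 : far[0] + 3, far[1] - 3 : far[1] + 3] = True
        assert vasc.find_contacts(cell, net, mask) == []

    def test_contacted_tube_diameter_recovered(self):
        px = 0.5
        mask = tube_mask((100, 300), (10, 50), (290, 50), radius_px=8)  # 4 um radius
        net = vasc.skeletonize_vessels(mask, px)
        vasc.split_unique_vessels(net)
        cell = np.zeros_like(mask)
        cell[20:42, 140:170] = True  # touches the tube from above
        contacts = vasc.find_contacts(cell, net, mask)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.d_min == pytest.approx(8.0, abs=1.0)
        assert c.d_max == pytest.approx(8.0, abs=1.0)
        assert c.d_min <= c.d_mean <= c.d_max

    def test_cell_across_branch_counts_unique_vessels(self):
        mask = (
            tube_mask((200, 200), (10, 100), (110, 100), 5)
            | tube_mask((200, 200), (110, 100), (190, 60), 5)
            | tube_mask((200, 200), (110, 100), (190, 140), 5)
        )
        net = vasc.skeletonize_vessels(mask, 1.0)
        vasc.split_unique_vessels(net)
        assert net.n_unique == 2
        cell = np.zeros_like(mask)
        cell[80:130, 90:180] = True  # spans the branch point and both daughters
        contacts = vasc.find_contacts(cell, net, mask)
        assert len(contacts) == 2

    def test_planted_connection_classes_recovered(self, rng):
        params = SceneParams(shape=(2, 512, 512), n_vessel_branches=2, seed=6)
        truth, vmask = generate_vessel_network(params)
        px = params.pixel_size_um
        net = vasc.skeletonize_vessels(vmask, px)
        vasc.split_unique_vessels(net)
        shape = vmask.shape
        mid = (shape[1] * px / 2, shape[0] * px / 2)
        dist = ndi.distance_transform_edt(~vmask)
        far_ij = np.unravel_index(np.argmax(dist), dist.shape)
        far = (far_ij[1] * px, far_ij[0] * px)
        for cls in ("enveloping", "mural", "non-enveloping"):
            spec = CellSpec(
                area_um2=500.0,
                connection_class=cls,
                motifs=("end-foot",) if cls == "non-enveloping" else (),
            )
            # non-enveloping cells keep their body off the vessel and reach
            # it through the end-foot, as the generator's scenes do
            center = far if cls == "non-enveloping" else mid
            t = generate_astrocyte(spec, center, truth, seed=rng)
            cell = rasterize(t.polygon, shape, px)
            result = vasc.classify_connection(cell, net, vmask)
            assert result.label == cls, (cls, result)

    def test_classification_is_total_without_contacts(self):
        mask = tube_mask((100, 100), (10, 20), (90, 20), 4)
        net = vasc.skeletonize_vessels(mask, 1.0)
        vasc.split_unique_vessels(net)
        cell = np.zeros_like(mask)
        cell[70:90, 70:90] = True
        with pytest.warns(UserWarning, match="no vessel"):
            result = vasc.classify_connection(cell, net, mask)
        assert result.label == "non-enveloping"
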