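"""Multi-domain meshing: geometry, conformity, tagging, quality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from angiomt.image import BinaryImage, CONNECTED_VESSEL, TISSUE, SegmentedImage, classify_domains
from angiomt.mesh import (
    MeshQualityReport,
    element_quality,
    identify_boundary_sets,
    mesh_segmented_image,
    write_msh2,
)


class TestElementQuality:
    def test_equilateral_is_unity(self):
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        assert element_quality(tri) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_is_zero(self):
        assert element_quality(np.array([[0.0, 0], [1, 1], [2, 2]])) == 0.0

    def test_right_isoceles_hand_value(self):
        # A = 1/2, rms^2 = 4/3 -> Q = (4/sqrt(3))(1/2)/(4/3) = sqrt(3)/2
        tri = np.array([[0.0, 0], [1, 0], [0, 1]])
        assert element_quality(tri) == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    @given(
        st.lists(st.floats(-50, 50), min_size=6, max_size=6),
        st.floats(0.1, 10),
        st.floats(0, 2 * np.pi),
    )
    def test_bounded_and_similarity_invariant(self, flat, scale, angle):
        tri = np.array(flat).reshape(3, 2)
        q = element_quality(tri)
        assert 0.0 <= q <= 1.0
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        q2 = element_quality(scale * tri @ rot.T + 3.7)
        assert q2 == pytest.approx(q, abs=1e-8)


def _edge_counts(triangles):
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


class TestMeshSegmentedImage:
    def test_two_domain_halves_conform(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[:, 20:] = 1
        seg = SegmentedImage(labels, (TISSUE, CONNECTED_VESSEL), 5e-6, ("left", "right"))
        mesh = mesh_segmented_image(seg)
        # conforming: every edge is shared by <=2 triangles, no duplicates
        _, counts = _edge_counts(mesh.triangles)
        assert counts.max() <= 2
        # both domains present and tagged
        assert set(np.unique(mesh.tri_domain)) == {0, 1}

    def test_all_triangles_positively_oriented(self, network_mesh):
        p = network_mesh.tri_coords()
        signed = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        assert (signed > 0).all()

    def test_no_duplicate_nodes(self, network_mesh):
        from scipy.spatial import cKDTree

        tol = 1e-9 * np.hypot(*network_mesh.extent)
        pairs = cKDTree(network_mesh.nodes).query_pairs(tol)
        assert not pairs

    def test_bar_area_ratio_matches_pixel_coverage(self, bar_seg, bar_mesh):
        areas = bar_mesh.areas()
        vessel = bar_mesh.tri_domain == bar_mesh.domain_index(CONNECTED_VESSEL)
        ratio = areas[vessel].sum() / areas.sum()
        pixel_ratio = bar_seg.class_mask(CONNECTED_VESSEL).mean()
        assert ratio == pytest.approx(pixel_ratio, rel=0.02)

    def test_bar_interface_length_twice_bar_length(self, bar_mesh):
        # 20 px tall full-width bar: walls are two straight 100 px lines
        d = bar_mesh.nodes[bar_mesh.interface_edges[:, 1]] - bar_mesh.nodes[bar_mesh.interface_edges[:, 0]]
        total = np.hypot(d[:, 0], d[:, 1]).sum()
        w_phys = bar_mesh.extent[0]
        assert total == pytest.approx(2 * w_phys, rel=0.02)

    def test_interface_edges_separate_vessel_from_tissue(self, network_mesh):
        conn = network_mesh.domain_index(CONNECTED_VESSEL)
        edge_map = {}
        for t_idx, tri in enumerate(network_mesh.triangles):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = tuple(sorted((tri[a], tri[b])))
                edge_map.setdefault(key, []).append(t_idx)
        for a, b in network_mesh.interface_edges:
            owners = edge_map[(min(a, b), max(a, b))]
            doms = {network_mesh.tri_domain[t] == conn for t in owners}
            assert doms == {True, False}

    def test_single_class_segmentation_rejected(self):
        seg = SegmentedImage(np.zeros((10, 10), dtype=np.int32), (TISSUE,))
        with pytest.raises(ValueError, match="2 domain classes"):
            mesh_segmented_image(seg)

    def test_domain_area_error_decreases_under_refinement(self, bar_seg):
        # refine element size and boundary-simplification tolerance together:
        # the area error is floored by the simplification tolerance, so both
        # must shrink for the tagged area to converge to the pixel count
        errors = []
        pixel_ratio = bar_seg.class_mask(CONNECTED_VESSEL).mean()
        for h_px, tol in ((8.0, 1.6), (4.0, 0.8), (2.0, 0.4)):
            mesh = mesh_segmented_image(
                bar_seg, max_element_size=h_px * bar_seg.pixel_pitch, simplify_tol_px=tol
            )
            areas = mesh.areas()
            vessel = mesh.tri_domain == mesh.domain_index(CONNECTED_VESSEL)
            errors.append(abs(areas[vessel].sum() / areas.sum() - pixel_ratio))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < errors[0]


class TestBoundarySets:
    def test_full_width_bar_has_inlets_on_both_faces(self, bar_mesh):
        x = bar_mesh.nodes[bar_mesh.inlet_nodes, 0]
        w = bar_mesh.extent[0]
        assert (x < 0.5 * bar_mesh.pixel_pitch).any()
        assert (x > w - 0.5 * bar_mesh.pixel_pitch).any()

    def test_isolated_blob_only_raises(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:18, 10:18] = True
        seg = classify_domains(BinaryImage(mask, 5e-6))
        mesh = mesh_segmented_image(seg)
        with pytest.raises(ValueError, match="inlet"):
            identify_boundary_sets(mesh)


class TestQuality:
    def test_network_mesh_meets_quality_targets(self, network_mesh):
        rep = MeshQualityReport.from_mesh(network_mesh)
        assert rep.mean_quality > 0.9
        assert (rep.per_element_quality < 0.05).sum() == 0
        assert rep.min_quality >= 0.0 and rep.per_element_quality.max() <= 1.0


def test_msh2_writer_round_trips_counts(tmp_path, bar_mesh):
    path = tmp_path / "bar.msh"
    write_msh2(bar_mesh, str(path))
    text = path.read_text().splitlines()
    n_nodes = int(text[text.index("$Nodes") + 1])
    n_elem = int(text[text.index("$Elements") + 1])
    assert n_nodes == bar_mesh.n_nodes
    assert n_elem == bar_mesh.n_triangles
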