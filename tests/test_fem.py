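"""Finite-element core: assembly, boundary conditions, two-stage solve."""

import numpy as np
import pytest

from angiomt.fem import (
    LinearSystem,
    ReactionSpec,
    TransportParams,
    apply_wall_flux,
    assemble_stiffness,
    conservation_report,
    edge_lengths,
    lumped_node_areas,
    solve_tissue_phase,
    solve_transport,
    solve_vessel_phase,
)
from angiomt.fixtures import generate_analytic_case

from angiomt.mesh import rect_mesh


class TestAssembly:
    def test_unit_right_triangle_hand_integration(self):
        K = assemble_stiffness(
            np.array([[0.0, 0], [1, 0], [0, 1]]), np.array([[0, 1, 2]]), 1.0
        ).toarray()
        expected = 0.5 * np.array([[2, -1, -1], [-1, 1, 0], [-1, 0, 1]])
        assert np.allclose(K, expected, atol=1e-14)

    def test_row_sums_vanish_and_symmetric(self):
        mesh = rect_mesh(5, 4, 1.0, 0.8)
        K = assemble_stiffness(mesh.nodes, mesh.triangles, 2.0)
        assert np.allclose(np.asarray(K.sum(axis=1)).ravel(), 0.0, atol=1e-12)
        assert abs(K - K.T).max() < 1e-14

    def test_linear_in_diffusivity(self):
        mesh = rect_mesh(3, 3, 1.0, 1.0)
        K1 = assemble_stiffness(mesh.nodes, mesh.triangles, 1.0)
        K2 = assemble_stiffness(mesh.nodes, mesh.triangles, 2.0)
        assert abs(K2 - 2 * K1).max() < 1e-14

    def test_zero_area_triangle_named(self):
        nodes = np.array([[0.0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError, match="element index 0"):
            assemble_stiffness(nodes, np.array([[0, 1, 2]]), 1.0)


class TestDirichlet:
    def test_all_constrained_returns_values(self):
        mesh = rect_mesh(4, 4, 1.0, 1.0)
        K = assemble_stiffness(mesh.nodes, mesh.triangles, 1.0)
        sys = LinearSystem(K, np.zeros(mesh.n_nodes))
        sys.apply_dirichlet(np.arange(mesh.n_nodes), 1.0)
        assert np.allclose(sys.solve(), 1.0)

    def test_strip_linear_profile_machine_precision(self):
        case = generate_analytic_case("strip_linear")
        mesh, C = case.solve(0)
        assert np.abs(C - case.reference(mesh.nodes)).max() < 1e-12

    def test_single_inlet_no_flux_gives_constant(self):
        mesh = rect_mesh(6, 6, 1.0, 1.0)
        K = assemble_stiffness(mesh.nodes, mesh.triangles, 1.0)
        sys = LinearSystem(K, np.zeros(mesh.n_nodes))
        sys.apply_dirichlet(np.array([0]), 1.0)
        assert np.allclose(sys.solve(), 1.0, atol=1e-10)


class TestWallFlux:
    def test_zero_flux_is_natural_boundary(self):
        mesh = rect_mesh(6, 3, 1.0, 0.5)
        F = np.zeros(mesh.n_nodes)
        edges = np.array([[0, 1], [1, 2]])
        apply_wall_flux(F, mesh.nodes, edges, 0.0)
        assert not F.any()

    def test_total_load_equals_P_times_length(self):
        rng = np.random.default_rng(3)
        nodes = rng.random((10, 2))
        edges = np.array([[0, 1], [2, 3], [4, 5]])
        F = np.zeros(10)
        P = 0.7
        apply_wall_flux(F, nodes, edges, P)
        assert F.sum() == pytest.approx(-P * edge_lengths(nodes, edges).sum(), rel=1e-12)

    def test_leaky_fin_matches_parabolic_closed_form(self):
        case = generate_analytic_case("leaky_fin")
        mesh, C = case.solve(0)
        vessel = case.region_mask(mesh)
        ref = case.reference(mesh.nodes)
        assert np.abs(C[vessel] - ref[vessel]).max() < 0.01
        # minimum sits at mid-length
        xm = mesh.nodes[vessel][np.argmin(C[vessel]), 0]
        assert xm == pytest.approx(mesh.extent[0] / 2, abs=0.1 * mesh.extent[0])


class TestVesselPhase:
    def test_impermeable_bar_is_uniform_at_inlet_value(self, bar_mesh):
        params = TransportParams(P_vessel=0.0)
        sol = solve_vessel_phase(bar_mesh, params)
        assert np.allclose(sol.C_vessel, 1.0, atol=1e-10)

    def test_leaky_bar_max_at_inlets_interior_below(self, bar_mesh):
        params = TransportParams(P_vessel=5e-8, D_vessel=3e-9, C_inlet=1.0)
        sol = solve_vessel_phase(bar_mesh, params)
        assert sol.C_vessel.max() == pytest.approx(1.0, abs=1e-12)
        x = bar_mesh.nodes[sol.vessel_nodes, 0]
        interior = (x > 0.1 * bar_mesh.extent[0]) & (x < 0.9 * bar_mesh.extent[0])
        assert (sol.C_vessel[interior] < 1.0).all()

    def test_no_connected_vessel_raises(self):
        from angiomt.image import BinaryImage, classify_domains
        from angiomt.mesh import mesh_segmented_image

        mask = np.zeros((30, 30), dtype=bool)
        mask[10:18, 10:18] = True
        seg = classify_domains(BinaryImage(mask, 5e-6))
        mesh = mesh_segmented_image(seg)
        with pytest.raises(ValueError, match="impossible"):
            solve_vessel_phase(mesh, TransportParams())


class TestTissuePhase:
    def test_no_reaction_harmonic_field_is_constant(self, bar_mesh):
        params = TransportParams(P_vessel=0.0)
        sol = solve_transport(bar_mesh, params)
        assert np.allclose(np.nan_to_num(sol.C_full), 1.0, atol=1e-9)

    def test_annulus_constant_sink_within_one_percent(self):
        case = generate_analytic_case("annulus_sink")
        mesh, C = case.solve(2)
        ref = case.reference(mesh.nodes)
        assert np.abs(C - ref).max() / np.abs(ref).max() < 0.01

    def test_interface_handoff_values_match_vessel_solution(self, mm_solution, network_mesh):
        sol, _ = mm_solution
        fixed = np.fromiter(sol._tissue_system.dirichlet.keys(), dtype=int)
        handoff = np.intersect1d(np.intersect1d(fixed, sol.vessel_nodes), sol.tissue_nodes)
        vals = np.fromiter(
            (sol._tissue_system.dirichlet[int(i)] for i in handoff), dtype=float
        )
        assert np.array_equal(sol.C_full[handoff], vals)

    def test_strong_constant_sink_warns_about_negative_concentration(self, network_mesh):
        params = TransportParams.demo("constant")
        with pytest.warns(UserWarning, match="negative tissue concentration"):
            sol = solve_transport(network_mesh, params)
        assert any("negative" in n for n in sol.notes)

    def test_maximum_principle_pure_diffusion(self, bar_mesh):
        params = TransportParams(P_vessel=1e-8)
        sol = solve_transport(bar_mesh, params)
        C = np.nan_to_num(sol.C_full)
        assert C.max() <= 1.0 + 1e-12
        assert C.min() >= np.nan_to_num(sol.C_vessel).min() - 1e-9


class TestPicard:
    def test_zero_rate_converges_immediately_to_no_reaction(self, network_mesh):
        params = TransportParams.demo("mm")
        params.reactions["tissue"] = ReactionSpec.michaelis_menten(0.0, 1e-3)
        sol = solve_transport(network_mesh, params)
        base = solve_transport(network_mesh, TransportParams.demo("none"))
        assert sol.picard_iterations <= 2
        assert np.allclose(
            np.nan_to_num(sol.C_full), np.nan_to_num(base.C_full), atol=1e-9
        )

    def test_converges_below_tolerance_on_network(self, mm_solution):
        sol, _ = mm_solution
        assert sol.converged
        assert sol.picard_iterations < 100
        assert sol.picard_residual < 1e-6

    def test_normalized_field_within_unit_interval(self, mm_solution):
        sol, _ = mm_solution
        C = np.nan_to_num(sol.C_full)
        assert C.min() > -1e-9 and C.max() <= 1.0 + 1e-12


class TestConservation:
    def test_constant_sink_balance_to_solver_precision(self, network_mesh):
        params = TransportParams.demo("constant")
        params.reactions["tissue"] = ReactionSpec.constant(2e-3)
        sol = solve_transport(network_mesh, params)
        rep = conservation_report(sol)
        assert rep["vessel_imbalance_rel"] < 1e-6
        assert rep["tissue_imbalance_rel"] < 1e-6

    def test_first_order_balance(self, network_mesh):
        params = TransportParams.demo("constant")
        params.reactions["tissue"] = ReactionSpec.first_order(0.05)
        sol = solve_transport(network_mesh, params)
        rep = conservation_report(sol)
        assert rep["tissue_imbalance_rel"] < 1e-6


def test_reaction_spec_validation():
    with pytest.raises(ValueError, match="kind"):
        ReactionSpec("quadratic")
    with pytest.raises(ValueError, match="K_M"):
        ReactionSpec("michaelis_menten", R_max=1.0, K_M=0.0)
    with pytest.raises(ValueError, match="R_max"):
        ReactionSpec("constant", R_max=-1.0)


def test_transport_params_validation():
    with pytest.raises(ValueError):
        TransportParams(D_vessel=0.0)
    with pytest.raises(ValueError):
        TransportParams(C_inlet=-1.0)
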