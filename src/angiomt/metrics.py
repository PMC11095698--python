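"""Perfusion metrics summarizing one solved network image.

* ``vessel_coverage`` — fraction of image pixels that are vessel.
* ``total_flux`` — summed outward wall flux over the vessel-tissue
  interface (the wall flux is prescribed, so this is P * total interface
  length, per unit depth).
* ``vascular_oxygen`` — area-averaged normalized concentration over the
  vessel domains (network oxygen-carrying capacity).
* ``oxygen_delivery`` — area-averaged normalized concentration over the
  tissue and organ domains (net oxygen delivered to tissue).
* ``connectivity`` — length-averaged normalized concentration over
  right-edge vessel nodes when oxygen enters from the left edge only
  (end-to-end transport, the computational analogue of a dextran
  perfusion assay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .image import CONNECTED_VESSEL, DISCONNECTED_VESSEL, TISSUE, SegmentedImage
from .mesh import TriMesh, _nodes_on_face
from .fem import (
    FieldSolution,
    LinearSystem,
    TransportParams,
    apply_wall_flux,
    assemble_stiffness,
    edge_lengths,
)


@dataclass
class MetricsReport:
    vessel_coverage: float
    total_flux: float
    total_flux_normalized: float
    vascular_oxygen: float
    oxygen_delivery: float
    connectivity: float
    picard_iterations: int = 0
    picard_residual: float = 0.0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "vessel_coverage": self.vessel_coverage,
            "total_flux": self.total_flux,
            "total_flux_normalized": self.total_flux_normalized,
            "vascular_oxygen": self.vascular_oxygen,
            "oxygen_delivery": self.oxygen_delivery,
            "connectivity": self.connectivity,
            "picard_iterations": self.picard_iterations,
            "picard_residual": self.picard_residual,
            "converged": self.converged,
        }


def vessel_coverage(seg: SegmentedImage) -> float:
    """Fraction of pixels classified as vessel (connected or not)."""
    return float(seg.vessel_mask().sum()) / seg.labels.size


def _area_average(sol: FieldSolution, mesh: TriMesh, tri_idx: np.ndarray) -> float:
    if len(tri_idx) == 0:
        return float("nan")
    areas = mesh.areas()[tri_idx]
    cbar = np.nan_to_num(sol.C_full)[mesh.triangles[tri_idx]].mean(axis=1)
    return float((areas * cbar).sum() / areas.sum())


def vascular_oxygen(sol: FieldSolution, mesh: TriMesh) -> float:
    """Area-averaged normalized oxygen over the vessel domains."""
    return _area_average(sol, mesh, mesh.domain_triangles(CONNECTED_VESSEL, DISCONNECTED_VESSEL))


def oxygen_delivery(sol: FieldSolution, mesh: TriMesh) -> float:
    """Area-averaged normalized oxygen over tissue and organ domains."""
    names = [c for c in mesh.domain_classes if c == TISSUE or c.startswith("organ:")]
    return _area_average(sol, mesh, mesh.domain_triangles(*names))


def total_flux(sol: FieldSolution, mesh: TriMesh, params: TransportParams) -> tuple[float, float]:
    """(dimensional, normalized) summed outward wall flux.

    The wall condition prescribes a constant flux density, so the total
    is P_vessel times the traced interface length (mol/s per meter of
    depth); the normalized variant divides by the inlet concentration.
    Recovered per-element flux vectors live on the solution object for
    visualization and are not used here.
    """
    edges = sol.mesh.interface_edges
    if sol._vessel_system is not None:
        # restrict to the edges that actually carried wall flux
        from .fem import _vessel_interface_edges

        edges = _vessel_interface_edges(mesh, sol.vessel_nodes)
    L = edge_lengths(mesh.nodes, edges).sum()
    return float(params.P_vessel * L), float(params.P_vessel / params.C_inlet * L)


def connectivity(mesh: TriMesh, params: TransportParams) -> float:
    """End-to-end network transport with a left-only inlet.

    The vessel phase is re-solved on the sub-network reachable from the
    left image face (the connected/disconnected split changes when only
    one inlet is assumed), and the resulting concentration is averaged,
    weighted by boundary segment length, over vessel nodes on the right
    image face. Returns 0 when no vessel path reaches the right edge.
    """
    vessel_names = [c for c in (CONNECTED_VESSEL, DISCONNECTED_VESSEL) if c in mesh.domain_classes]
    if not vessel_names:
        return 0.0
    vtris_idx = mesh.domain_triangles(*vessel_names)
    if len(vtris_idx) == 0:
        return 0.0
    tris = mesh.triangles[vtris_idx]
    n = mesh.n_nodes
    rows = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 2]])
    cols = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0]])
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = connected_components(adj + adj.T, directed=False)

    vnodes_all = np.unique(tris)
    left = np.intersect1d(_nodes_on_face(mesh, "left"), vnodes_all)
    if len(left) == 0:
        return 0.0
    left_comps = np.unique(comp[left])
    keep = np.isin(comp[tris[:, 0]], left_comps)
    tris_l = tris[keep]
    if len(tris_l) == 0:
        return 0.0
    vnodes = np.unique(tris_l)

    right = np.intersect1d(_nodes_on_face(mesh, "right"), vnodes)
    if len(right) == 0:
        return 0.0

    # wall edges of the left-connected sub-network: boundary edges between
    # a kept vessel triangle and a non-vessel triangle
    kept_tri_idx = vtris_idx[keep]
    all_tris = mesh.triangles
    e = np.vstack([all_tris[:, [0, 1]], all_tris[:, [1, 2]], all_tris[:, [2, 0]]])
    e.sort(axis=1)
    in_kept = np.tile(np.isin(np.arange(mesh.n_triangles), kept_tri_idx), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    es, ks = e[order], in_kept[order]
    same = (np.diff(es, axis=0) == 0).all(axis=1)
    first = np.flatnonzero(same)
    mixed = ks[first] != ks[first + 1]
    wall_edges = es[first[mixed]]

    K = assemble_stiffness(mesh.nodes, tris_l, params.D_vessel)
    F = np.zeros(n)
    apply_wall_flux(F, mesh.nodes, wall_edges, params.P_vessel / params.C_inlet)
    sys = LinearSystem(K, F)
    sys.apply_dirichlet(left, 1.0)
    sys.apply_dirichlet(np.setdiff1d(np.arange(n), vnodes), 0.0)
    C = sys.solve()

    # length weights: edges of kept triangles with both endpoints on the right face
    te = np.vstack([tris_l[:, [0, 1]], tris_l[:, [1, 2]], tris_l[:, [2, 0]]])
    te.sort(axis=1)
    te = np.unique(te, axis=0)
    redges = te[np.isin(te, right).all(axis=1)]
    if len(redges) == 0:
        return float(np.mean(C[right]))
    w = np.zeros(n)
    L = edge_lengths(mesh.nodes, redges)
    for (a, b), length in zip(redges, L):
        w[a] += length / 2.0
        w[b] += length / 2.0
    wr = w[right]
    return float((wr * C[right]).sum() / wr.sum())


def compute_metrics(
    seg: SegmentedImage,
    mesh: TriMesh,
    sol: FieldSolution,
    params: TransportParams,
) -> MetricsReport:
    """All perfusion metrics for one solved image."""
    flux_dim, flux_norm = total_flux(sol, mesh, params)
    return MetricsReport(
        vessel_coverage=vessel_coverage(seg),
        total_flux=flux_dim,
        total_flux_normalized=flux_norm,
        vascular_oxygen=vascular_oxygen(sol, mesh),
        oxygen_delivery=oxygen_delivery(sol, mesh),
        connectivity=connectivity(mesh, params),
        picard_iterations=sol.picard_iterations,
        picard_residual=sol.picard_residual,
        converged=sol.converged,
    )
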