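"""Synthetic vessel-network images and analytic validation cases.

``generate_network`` draws branching random-walk trees rasterized by
disk-stamping, emulating the morphology of self-assembled microvascular
networks over a ~1 mm field: controllable coverage, guaranteed
left-right spanning paths, and disconnected "islands". It is the test
bed for every pipeline stage in place of wet-lab image data.

``generate_analytic_case`` builds small problems with closed-form
solutions (linear strip, constant-sink annulus, leaky fin) used to
validate the finite-element core against exact references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .image import (
    BinaryImage,
    CONNECTED_VESSEL,
    SegmentedImage,
    TISSUE,
    classify_domains,
)
from .mesh import TriMesh, annulus_mesh, mesh_segmented_image, rect_mesh
from .fem import (
    LinearSystem,
    ReactionSpec,
    TransportParams,
    assemble_stiffness,
    lumped_node_areas,
    solve_vessel_phase,
)

#: fixture pixel pitch: 5 um/pixel, so a 200x200 fixture is a 1x1 mm ROI
FIXTURE_PIXEL_PITCH = 5.0e-6


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic vessel-network image.

    The random-walk tree grows from seed points with normally
    distributed heading changes (``wiggle``, radians) every ``step_px``
    pixels, branching with probability ``branch_prob`` per step, and is
    rasterized by stamping disks of diameter ``vessel_width_px``. Growth
    stops when ``target_coverage`` is reached. ``ensure_spanning`` seeds
    one walk that is steered across the full image width so at least one
    component touches both left and right faces; ``islands`` adds that
    many blobs guaranteed to touch no inlet face and no other component.
    """

    shape: tuple[int, int] = (200, 200)
    n_seeds: int = 4
    step_px: float = 4.0
    wiggle: float = 0.45
    branch_prob: float = 0.12
    vessel_width_px: int = 7
    target_coverage: float = 0.3
    ensure_spanning: bool = True
    islands: int = 0
    island_coverage: float = 0.0
    x_band: tuple[float, float] = (0.0, 1.0)
    organ: dict | None = None
    seed: int = 0
    pixel_pitch: float = FIXTURE_PIXEL_PITCH

    def __post_init__(self) -> None:
        if not 0.0 < self.target_coverage < 1.0:
            raise ValueError("target_coverage must lie in (0, 1)")
        if self.vessel_width_px < 1:
            raise ValueError("vessel_width_px must be >= 1")
        if not 0.0 <= self.island_coverage < self.target_coverage + 1e-12:
            raise ValueError("island_coverage must lie in [0, target_coverage]")
        c0, c1 = self.x_band
        if not (0.0 <= c0 < c1 <= 1.0):
            raise ValueError("x_band must satisfy 0 <= lo < hi <= 1")
        if c0 > 0.0 and c1 < 1.0:
            raise ValueError("x_band must include the left or the right image face")


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dy ** 2 + dx ** 2 <= radius ** 2
    return dy[inside], dx[inside]


def _stamp(
    mask: np.ndarray, row: float, col: float, offs, forbidden: np.ndarray | None = None
) -> bool:
    """Stamp a disk; refuse (returning False) if it touches forbidden pixels."""
    dy, dx = offs
    h, w = mask.shape
    rr = np.clip(np.round(row + dy).astype(int), 0, h - 1)
    cc = np.clip(np.round(col + dx).astype(int), 0, w - 1)
    if forbidden is not None and forbidden[rr, cc].any():
        return False
    mask[rr, cc] = True
    return True


def _walk(
    rng: np.random.Generator,
    mask: np.ndarray,
    start: tuple[float, float],
    heading: float,
    spec: FixtureSpec,
    offs,
    n_steps: int,
    col_range: tuple[int, int] | None = None,
    forbidden: np.ndarray | None = None,
) -> list[tuple[tuple[float, float], float]]:
    """Stamp one random walk; returns branch (position, heading) events."""
    h, w = mask.shape
    c_lo, c_hi = (0, w) if col_range is None else col_range
    row, col = start
    branches = []
    for _ in range(n_steps):
        if not _stamp(mask, row, col, offs, forbidden):
            break
        heading += rng.normal(0.0, spec.wiggle)
        row += spec.step_px * np.sin(heading)
        col += spec.step_px * np.cos(heading)
        if not (0 <= row < h and c_lo <= col < c_hi):
            row = float(np.clip(row, 0, h - 1))
            col = float(np.clip(col, c_lo, c_hi - 1))
            break
        if rng.random() < spec.branch_prob:
            branches.append(((row, col), heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.4)))
    return branches


def _grow_main_network(
    rng: np.random.Generator,
    spec: FixtureSpec,
    islands_mask: np.ndarray,
) -> np.ndarray:
    """Grow the inlet-seeded network up to the total coverage target,
    steering around a guard zone so islands stay disconnected."""
    h, w = spec.shape
    c_lo = int(round(spec.x_band[0] * w))
    c_hi = int(round(spec.x_band[1] * w))
    mask = np.zeros((h, w), dtype=bool)
    offs = _disk_offsets(spec.vessel_width_px / 2.0)
    total = h * w
    island_area = islands_mask.sum() / total
    target = spec.target_coverage - island_area
    has_left = c_lo == 0
    has_right = c_hi == w
    forbidden = (
        ndimage.binary_dilation(islands_mask, np.ones((3, 3)), iterations=2)
        if islands_mask.any()
        else None
    )

    if spec.ensure_spanning and has_left and has_right:
        row = rng.uniform(0.25 * h, 0.75 * h)
        col, heading = 0.0, 0.0
        prev = (row, col)
        n_guard = int(10 * w / spec.step_px)
        for _ in range(n_guard):
            if _stamp(mask, row, col, offs, forbidden):
                prev = (row, col)
                if col >= w - 1:
                    break
                heading = 0.6 * (heading + rng.normal(0.0, spec.wiggle))
            else:
                # blocked by an island guard zone: back up and turn, so the
                # stamped path stays contiguous while we slide around it
                row, col = prev
                heading += rng.choice([-1.0, 1.0]) * 1.0
            row = float(np.clip(row + spec.step_px * np.sin(heading), 1, h - 2))
            col += spec.step_px * abs(np.cos(heading))
        mask[:, -1] |= mask[:, -2]  # guarantee right-face touch after clipping

    queue: list[tuple[tuple[float, float], float]] = []
    faces = [f for f, ok in (("left", has_left), ("right", has_right)) if ok]
    for _ in range(spec.n_seeds):
        face = faces[rng.integers(len(faces))]
        row = rng.uniform(0, h - 1)
        col = float(c_lo) if face == "left" else float(c_hi - 1)
        queue.append(((row, col), rng.uniform(-np.pi / 3, np.pi / 3) + (0.0 if face == "left" else np.pi)))

    steps_per_walk = max(8, int(0.25 * w / spec.step_px))
    for _ in range(6000):
        if mask.sum() / total >= target:
            break
        if not queue:
            ys, xs = np.nonzero(mask)
            i = rng.integers(len(ys))
            queue.append(((float(ys[i]), float(xs[i])), rng.uniform(-np.pi, np.pi)))
        start, heading = queue.pop(rng.integers(len(queue)))
        queue.extend(
            _walk(rng, mask, start, heading, spec, offs, steps_per_walk,
                  col_range=(c_lo, c_hi), forbidden=forbidden)
        )
    else:
        warnings.warn(
            f"target coverage {target:.2f} not reached "
            f"(got {mask.sum() / total:.2f}); best effort",
            stacklevel=3,
        )
    return mask


def _grow_islands(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    """Stamp ``spec.islands`` blobs touching no inlet face and not each other.

    When ``island_coverage`` is set, each island grows as a wandering
    walk until it reaches its share of that pixel budget; otherwise each
    island is a compact 3-step blob.
    """
    h, w = spec.shape
    mask = np.zeros((h, w), dtype=bool)
    offs = _disk_offsets(spec.vessel_width_px / 2.0)
    margin = spec.vessel_width_px + 3
    quota = (
        spec.island_coverage * h * w / spec.islands if spec.island_coverage > 0 else 0.0
    )
    for _ in range(spec.islands):
        placed = False
        for _attempt in range(200):
            row = rng.uniform(margin, h - margin)
            col = rng.uniform(margin, w - margin)
            cand = np.zeros_like(mask)
            heading = rng.uniform(-np.pi, np.pi)
            r, c = row, col
            n_steps = 3 if quota == 0 else 400
            for _ in range(n_steps):
                _stamp(cand, r, c, offs)
                if quota and cand.sum() >= quota:
                    break
                heading += rng.normal(0.0, spec.wiggle)
                r_new = r + spec.step_px * np.sin(heading)
                c_new = c + spec.step_px * np.cos(heading)
                if not (margin <= r_new <= h - margin and margin <= c_new <= w - margin):
                    # bounce back toward the interior and keep growing
                    heading += np.pi / 2
                    r_new = float(np.clip(r_new, margin, h - margin))
                    c_new = float(np.clip(c_new, margin, w - margin))
                r, c = r_new, c_new
            if cand[:, 0].any() or cand[:, -1].any():
                continue
            grown = ndimage.binary_dilation(cand, np.ones((3, 3)), iterations=2)
            if (grown & mask).any():
                continue
            mask |= cand
            placed = True
            break
        if not placed:
            warnings.warn("could not place a disconnected island; skipping", stacklevel=3)
    return mask


def generate_network(spec: FixtureSpec) -> BinaryImage:
    """Generate one synthetic binary vessel-network image.

    Deterministic for a fixed spec (single seeded generator); measured
    coverage tracks ``target_coverage`` to within a few percentage
    points (disk stamping overshoots by at most one disk area).
    """
    rng = np.random.default_rng(spec.seed)
    islands = (
        _grow_islands(rng, spec)
        if spec.islands
        else np.zeros(spec.shape, dtype=bool)
    )
    mask = _grow_main_network(rng, spec, islands)
    return BinaryImage(mask | islands, spec.pixel_pitch)


def coverage_sweep_spec(
    coverage: float,
    seed: int,
    shape: tuple[int, int] = (200, 200),
    x_band: tuple[float, float] = (0.0, 1.0),
) -> FixtureSpec:
    """Fixture family emulating the coverage-dependence of real networks.

    Self-assembled networks percolate with density: sparse cultures are
    dominated by disconnected cords, dense ones form spanning, inlet-
    connected networks. The family encodes that by letting the island
    share of the vessel area fall linearly from ~85% at 10% coverage to
    zero at >=45% coverage, with a guaranteed spanning path only in the
    percolated regime. ``x_band`` confines the main network horizontally
    to vary inlet proximity at fixed coverage.
    """
    frac = float(np.clip(0.85 * (0.45 - coverage) / 0.35, 0.0, 0.85))
    n_islands = max(1, round(6 * frac)) if frac > 0 else 0
    return FixtureSpec(
        shape=shape,
        target_coverage=coverage,
        island_coverage=frac * coverage,
        islands=n_islands,
        ensure_spanning=coverage >= 0.25 and x_band == (0.0, 1.0),
        x_band=x_band,
        seed=seed,
    )


def organ_disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disk mask for embedding an organ (islet) region."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# analytic validation cases


@dataclass
class AnalyticCase:
    """A solvable problem paired with its closed-form reference field.

    ``build(level)`` returns a mesh refined ``2**level`` times;
    ``solve(level)`` returns (mesh, nodal field); ``reference(points)``
    evaluates the exact solution at (n, 2) coordinates.
    """

    name: str
    build: Callable[[int], TriMesh]
    solve_on: Callable[[TriMesh], np.ndarray]
    reference: Callable[[np.ndarray], np.ndarray]
    region_mask: Callable[[TriMesh], np.ndarray] | None = None

    def solve(self, level: int = 0) -> tuple[TriMesh, np.ndarray]:
        mesh = self.build(level)
        return mesh, self.solve_on(mesh)


def _strip_linear_case() -> AnalyticCase:
    """1D diffusion across a strip: C(0)=1, C(L)=0, exact linear profile."""
    L, H, D = 1.0e-3, 2.0e-4, 3.0e-9

    def build(level: int) -> TriMesh:
        f = 2 ** level
        return rect_mesh(20 * f, 4 * f, L, H, CONNECTED_VESSEL)

    def solve_on(mesh: TriMesh) -> np.ndarray:
        K = assemble_stiffness(mesh.nodes, mesh.triangles, D)
        sys = LinearSystem(K, np.zeros(mesh.n_nodes))
        x = mesh.nodes[:, 0]
        sys.apply_dirichlet(np.flatnonzero(x < 1e-12), 1.0)
        sys.apply_dirichlet(np.flatnonzero(x > L - 1e-12), 0.0)
        return sys.solve()

    return AnalyticCase(
        "strip_linear", build, solve_on, lambda p: 1.0 - np.asarray(p)[:, 0] / L
    )


#: annulus geometry/parameters shared by the case and its tests
ANNULUS = {"r0": 1.0e-4, "r1": 5.0e-4, "D": 2.0e-9, "R": 8.0e-3}


def annulus_reference(points: np.ndarray) -> np.ndarray:
    """Radial constant-sink closed form.

    For D laplacian(C) = R on r0 < r < r1 with C(r0)=1 and zero flux at
    r1: C(r) = 1 + (R/4D)(r^2 - r0^2) - (R r1^2 / 2D) ln(r/r0).
    """
    r0, r1, D, R = ANNULUS["r0"], ANNULUS["r1"], ANNULUS["D"], ANNULUS["R"]
    r = np.hypot(points[:, 0], points[:, 1])
    return 1.0 + (R / (4 * D)) * (r ** 2 - r0 ** 2) - (R * r1 ** 2 / (2 * D)) * np.log(r / r0)


def _annulus_sink_case() -> AnalyticCase:
    r0, r1, D, R = ANNULUS["r0"], ANNULUS["r1"], ANNULUS["D"], ANNULUS["R"]

    def build(level: int) -> TriMesh:
        f = 2 ** level
        return annulus_mesh(r0, r1, 8 * f, 48 * f, TISSUE)

    def solve_on(mesh: TriMesh) -> np.ndarray:
        K = assemble_stiffness(mesh.nodes, mesh.triangles, D)
        w = lumped_node_areas(mesh.nodes, mesh.triangles, mesh.n_nodes)
        F = -R * w
        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        sys = LinearSystem(K, F)
        sys.apply_dirichlet(np.flatnonzero(r < r0 * (1 + 1e-9)), 1.0)
        return sys.solve()

    return AnalyticCase("annulus_sink", build, solve_on, annulus_reference)


#: leaky-fin geometry/parameters shared by the case and its tests
LEAKY_FIN = {
    "shape": (40, 200),
    "bar_rows": (15, 25),
    "pitch": FIXTURE_PIXEL_PITCH,
    "P": 1.2e-7,
    "D": 3.0e-9,
}


def leaky_fin_segmentation() -> SegmentedImage:
    """Full-width vessel bar: inlets at both faces, permeable long walls."""
    h, w = LEAKY_FIN["shape"]
    r0, r1 = LEAKY_FIN["bar_rows"]
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r1, :] = True
    return classify_domains(BinaryImage(mask, LEAKY_FIN["pitch"]), ("left", "right"))


def leaky_fin_reference(points: np.ndarray) -> np.ndarray:
    """Uniform-wall-loss fin with both ends held at the inlet value.

    1D balance D w C'' = 2P gives the parabola
    C(x) = 1 + (P / (D w)) x (x - L), minimum at mid-length.
    """
    h, w_img = LEAKY_FIN["shape"]
    r0, r1 = LEAKY_FIN["bar_rows"]
    pitch, P, D = LEAKY_FIN["pitch"], LEAKY_FIN["P"], LEAKY_FIN["D"]
    L = w_img * pitch
    width = (r1 - r0) * pitch
    x = np.asarray(points)[:, 0]
    return 1.0 + (P / (D * width)) * x * (x - L)


def _leaky_fin_case() -> AnalyticCase:
    params = TransportParams(
        D_vessel=LEAKY_FIN["D"], P_vessel=LEAKY_FIN["P"], C_inlet=1.0
    )

    def build(level: int) -> TriMesh:
        seg = leaky_fin_segmentation()
        h = seg.pixel_pitch * (3.0 / 2 ** level)
        return mesh_segmented_image(seg, max_element_size=h)

    def solve_on(mesh: TriMesh) -> np.ndarray:
        sol = solve_vessel_phase(mesh, params)
        return sol.C_full

    def region(mesh: TriMesh) -> np.ndarray:
        vessel = np.zeros(mesh.n_nodes, dtype=bool)
        vessel[np.unique(mesh.triangles[mesh.domain_triangles(CONNECTED_VESSEL)])] = True
        return vessel

    return AnalyticCase("leaky_fin", build, solve_on, leaky_fin_reference, region)


_CASES = {
    "strip_linear": _strip_linear_case,
    "annulus_sink": _annulus_sink_case,
    "leaky_fin": _leaky_fin_case,
}


def generate_analytic_case(name: str) -> AnalyticCase:
    """Named validation problems with closed-form reference fields."""
    try:
        return _CASES[name]()
    except KeyError:
        raise ValueError(f"unknown analytic case {name!r}; choose from {sorted(_CASES)}")
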