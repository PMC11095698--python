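# Methods

## Problem and model

The package computes steady, convection-free oxygen transport in a 2D
cross-section of a vascularized tissue, taking the vessel geometry
verbatim from a binarized fluorescence image. The governing equation in
every domain is the stationary diffusion–reaction balance

    0 = −∇·(−D ∇C) + R(C)

with first-order (P1) triangular Galerkin finite elements. Transport is
solved in two one-way coupled stages that mirror the physiology:
oxygen enters through designated image faces ("inlets", default left and
right), travels through the inlet-connected vessel network, leaks
through the vessel wall, and is consumed in the tissue.

**Vessel phase.** The connected-vessel domain has no bulk reaction
(endothelium does not consume appreciably at this scale). Inlet-face
nodes carry a Dirichlet condition C = C_in; every vessel–tissue
interface edge carries a constant outward Neumann flux density P
(−D∇C·n̂ = −P), integrated consistently so each edge of length L loads
its end nodes with −P·L/2. P is taken literally as a flux density in
mol m⁻² s⁻¹ (the units its literature value is quoted in), not as a
permeability multiplying a concentration difference; with the default
magnitudes this choice is inconsequential (see "Parameter sets").

**Tissue phase.** Tissue, organ and disconnected-vessel domains are
solved together. Interface nodes inherit the vessel-phase
concentrations as Dirichlet values — a handoff, with no back-coupling
into the vessel solve. Disconnected vessels use the vessel diffusivity
and do not react; they are oxygenated only through the surrounding
tissue, which is what makes fragmented networks score poorly. Image
borders are natural (zero-flux). Reactions per domain:

* constant: R = R_max (load vector term, −R_max·A/3 per node);
* first-order: R = k₁C (lumped mass added to the stiffness diagonal);
* Michaelis–Menten: R = R_max·C/(K_M + C), solved by Picard iteration —
  each pass freezes the nodewise coefficient R_max/(K_M + Cᵏ) as an
  effective first-order rate, reassembles and re-solves, until the
  relative L2 change falls below `tol` (default 1e-6, cap 100
  iterations). If the residual rises while undamped, damping drops to
  0.5 automatically. Non-converged results are returned flagged.

All solves run normalized to the inlet concentration (C/C_in, lengths
in meters); Dirichlet constraints are imposed by elimination, and the
reduced symmetric systems go through sparse direct factorization
(meshes here are ≤ ~10⁵ nodes). Concentrations are reported normalized,
so consuming kinetics keep fields in [0, 1]. A constant sink can drive
concentrations negative in poorly supplied regions; the package warns
and reports rather than clamping, because clamping would silently
violate conservation — saturable (Michaelis–Menten) kinetics is the
physically meaningful choice in that regime.

**Conservation accounting.** From the assembled systems, the discrete
influx through Dirichlet node sets (residual K·C − F summed over
constrained nodes) is compared with the prescribed wall-flux total
(vessel phase) and with the total reaction uptake plus border outflux
(tissue phase). For linear kinetics these balance to solver precision
(~1e-12 relative); for Michaelis–Menten they agree to roughly the
Picard tolerance, since the frozen coefficient lags the final field by
one iteration.

## Segmentation

Images are normalized by dtype (8-bit /255, 16-bit /65535; floats
assumed normalized, clipped with a warning), thresholded at 0.2 by
default, and labeled with 8-connectivity — chosen so single-pixel
diagonal joins do not spuriously disconnect a vessel. Components
touching an inlet face are "connected vessel"; the rest are
"disconnected vessel"; background is tissue (no separate void class).
Organ regions may only overwrite tissue pixels — vessels win on
overlap — and an organ mask that covers no tissue at all is an error.
The N domains present get gray levels i/(N−1), stored as exact
rationals (the familiar 0.33/0.66 are display roundings of 1/3, 2/3),
tissue at 0 and connected vessel at 1.

## Meshing

No constrained-triangulation library is used; the multi-domain mesher
is built on plain Delaunay triangulation with a designed point set:

1. domain boundaries traced with marching squares (sub-pixel, on a
   zero-padded mask so border-touching regions close);
2. Douglas–Peucker simplification, tolerance 0.5–0.8 px (default 0.8);
   sub-pixel rings (< 0.5 px² area) are dropped with a warning;
3. re-grading: each straight stretch between simplification corners is
   split into equal segments no longer than the element size, and the
   per-stretch spacings are graded by cyclic min-plus propagation so
   adjacent spacings differ by at most a factor (1 + gradient_limit).
   The gradient limit semantics is this package's own (the parameter
   name follows common image-meshing practice but has no canonical
   definition); it is validated through the element-quality target. The
   gradation source is floored at 1 px so sub-pixel corners cannot
   cascade into runaway refinement;
4. a hexagonal interior lattice at the element size (default 2 px)
   fills the rectangle, minus an exclusion zone of 0.75·h around
   boundary points; near-duplicate points are merged at 0.2 px
   (union-find over KD-tree pairs);
5. Delaunay triangulation (Qhull), two Laplacian smoothing passes that
   move only interior lattice points, then up to two boundary-recovery
   passes that insert midpoints of any traced segment not present as a
   triangulation edge. Recovery runs last deliberately: smoothing after
   recovery can pull lattice points back into the diametral circles of
   recovered edges and un-recover them.
6. slivers with shape quality below 0.05 (areas a small fraction of a
   pixel, produced by near-coincident boundary points where two traced
   contours face each other) are culled;
7. each triangle inherits the domain of the pixel under its centroid
   (origin bottom-left, pixel centers at (i+0.5)·pitch); interface
   edges are read off triangle adjacency (an edge shared by a
   connected-vessel triangle and any other-domain triangle), which
   keeps the physics robust even where boundary recovery is imperfect;
   inlet nodes are connected-vessel nodes within half a pixel of an
   inlet face.

Because everything is one triangulation of one point set, domains
conform by construction. Element quality Q = (4/√3)·A/rms², rms² =
(a²+b²+c²)/3, is 1 iff equilateral; generated network meshes average
0.94–0.98 at the default settings (2 px elements, gradient limit 0.2).
Domain-tagged areas track pixel counts to ≲0.25%, floored by the
simplification tolerance; shrinking element size and tolerance together
drives the error to zero.

Connected-vessel triangles whose mesh component contains no inlet node
(possible through tagging noise at pinch points) are demoted to the
tissue phase so the vessel system stays nonsingular.

## Parameter sets

`TransportParams.table_defaults()` carries the literature values:
D_vessel = 3×10⁻⁹ m²/s, D_tissue = 2×10⁻⁹ m²/s, P = 2.75×10⁻¹⁴
mol m⁻² s⁻¹, R_max = 0.06×10⁻¹² mol m⁻³ s⁻¹, K_M = 10⁻³ mol m⁻³.
Taken together these magnitudes are internally inconsistent with any
visible oxygen depletion on a 1 mm domain: the wall-loss and Damköhler
numbers they imply are ~10⁻⁸–10⁻¹⁰, so every field is uniform at the
inlet value. They are kept verbatim as the configuration defaults, and
a separate, clearly named `TransportParams.demo()` set provides
physiologically scaled magnitudes for demonstrations and the synthetic
studies: C_in = 0.2 mol/m³ (air-saturated medium), R_max = 10⁻²
mol m⁻³ s⁻¹ — giving the classic Krogh-type penetration depth
√(D_t·C_in/R_max) ≈ 200 µm — K_M = 10⁻³ mol/m³, and P = 5×10⁻¹²
mol m⁻² s⁻¹, small enough (a few percent of the inlet value over a
1 mm leaky path) that thin vessels are not drained negative. These
values were fixed once from literature-scale tissue oxygen consumption
before any downstream results were computed. Note that in this model
tissue oxygenation is governed by the interface Dirichlet handoff and
R_max, not by P; P mainly shapes the small axial dips inside vessels
and the connectivity metric.

## Synthetic networks

`generate_network` emulates binarized vasculogenesis images at desk
scale: 200×200 px at 5 µm/px (the same 1×1 mm field as typical
experiments, at reduced resolution). Branching random walks grow from
inlet-face seeds (normally distributed heading changes, branching
probability 0.12 per step) and are rasterized by stamping disks of the
vessel width (7 px ≈ 35 µm, a realistic capillary-cord diameter), so
minimum width is guaranteed. Growth stops at the target coverage;
accuracy is within ±3 percentage points. Options force a left-to-right
spanning path, confine growth to a horizontal band (to vary inlet
proximity at fixed coverage), and add a controlled number of
disconnected islands with a guaranteed 2 px guard gap — grown first,
with the main network steering around them, so island counts are exact
by construction.

The `coverage_sweep_spec` family encodes the empirical property of
self-assembling cultures that sparse networks are fragmented: the
island share of vessel area falls linearly from ~85% at 10% coverage to
zero at ≥45%, where a spanning path is also guaranteed. This is what
produces the rising, saturating coverage–oxygenation curves and the
low-coverage scatter; a sweep holding fragmentation fixed would move
only the tissue-reaction part of the signal.

What the generator does **not** emulate: real intensity statistics and
staining noise (it produces masks directly), anastomosis loop
statistics, vessel taper and diameter distributions, and biological
growth mechanisms (no growth-factor fields or tip-cell rules). Passing
tests therefore demonstrate the correctness of the segmentation,
meshing, solver and metrics on realistic geometry, not predictive
accuracy for any particular biological dataset.

## Analytic validation cases

* `strip_linear` — pure diffusion across a rectangle, ends at 1 and 0:
  P1 reproduces the linear profile to machine precision.
* `annulus_sink` — constant sink between a unit-concentration inner
  circle (r₀ = 100 µm) and a no-flux outer circle (r₁ = 500 µm), closed
  form C(r) = 1 + (R/4D)(r²−r₀²) − (Rr₁²/2D)·ln(r/r₀); structured polar
  meshes show the expected ~O(h²) L2 convergence (fitted order ≈ 1.98).
* `leaky_fin` — image-derived full-width vessel bar with both ends at
  the inlet value and uniform wall loss: matches the fin parabola
  C(x) = 1 + (P/Dw)·x(x−L) within 1%.

The strip and annulus cases use directly constructed structured meshes
with custom Dirichlet maps, because their closed forms need boundary
values the image pathway cannot express; the leaky fin runs through the
full image → segmentation → mesh → vessel-phase pipeline.

## Numerical choices and degenerate inputs

* Dirichlet by elimination (not penalty): exact at constrained nodes,
  no conditioning penalty.
* Lumped (nodewise) reaction integration throughout, so the
  Michaelis–Menten linearization and its constant/first-order limits
  are discretized identically and the limit checks are meaningful.
* Node dedup tolerance 0.2 px at meshing; duplicate detection for mesh
  invariants at 10⁻⁹ × image diagonal.
* Zero-area triangles abort assembly with the element index named.
* Images with no vessel pixels segment to a single tissue class with a
  warning; solving requires a connected-vessel domain reaching an inlet
  and raises otherwise.
* Ties in centroid tagging (centroid exactly on a pixel edge) follow
  `floor`, i.e. the lower-index pixel; at the default sub-pixel element
  sizes this is measure-zero in practice.

## Problem sizes

Default study sizes were chosen for interactive turnaround on one core:
200×200 px fixtures mesh to ~10–25k triangles in ~1 s and solve in
well under a second; the full test suite (including the ten-network
quality study, a four-level convergence study and a twelve-solve
coverage sweep) runs in about a minute. The pipeline itself has no
hard-coded size limits; 1000×1000 px images at 1 µm/pitch mesh to a few
hundred thousand elements and remain within reach of the sparse direct
solver.

## Known limitations

* 2D only; no convective (flow) contribution; steady state only.
* One-way vessel→tissue coupling: the tissue field does not feed back
  into the wall flux, and the constant-P wall model is supply-agnostic —
  a long path can be drained below zero (warned, not clamped).
* The endothelial wall itself is not a diffusion barrier (wall
  thickness ~5–10 µm is negligible against the ~1000 µm domain).
* Interface flux is prescribed, so the "total flux" metric is geometric
  (P × interface length); recovered-gradient flux vectors are exposed
  separately for visualization only.
* Histogram-matched comparison against in-vivo oxygen micrographs
  requires external image data and is out of scope.
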