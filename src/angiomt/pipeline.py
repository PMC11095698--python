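"""End-to-end batch pipeline: images in, fields + metrics + figures out."""

from __future__ import annotations

import glob as globlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import image as im
from .fem import TransportParams, ReactionSpec, solve_transport
from .mesh import (
    MeshQualityReport,
    mesh_segmented_image,
    write_mesh_csv,
    write_msh2,
    write_quality_report,
)
from .metrics import compute_metrics

log = logging.getLogger("angiomt")


@dataclass
class RunConfig:
    """Configuration of one batch run (JSON-serializable)."""

    inputs: list[str] = field(default_factory=list)
    output_dir: str = "angiomt_out"
    threshold: float = 0.2
    inlet_faces: tuple[str, ...] = ("left", "right")
    pixel_pitch: float = im.DEFAULT_PIXEL_PITCH
    gradient_limit: float = 0.2
    max_element_size_px: float = 2.0
    kinetics: str = "constant"
    demo_params: bool = False
    D_vessel: float | None = None
    D_tissue: float | None = None
    P_vessel: float | None = None
    C_inlet: float | None = None
    R_max: float | None = None
    K_M: float | None = None
    organ_R_max: float | None = None
    picard_tol: float = 1e-6
    picard_max_iter: int = 100
    seed: int = 0
    figures: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if not 0.0 < self.gradient_limit <= 1.0:
            raise ValueError("gradient_limit must lie in (0, 1]")
        if self.max_element_size_px <= 0 or self.pixel_pitch <= 0:
            raise ValueError("sizes must be positive")

    def transport_params(self) -> TransportParams:
        base = (
            TransportParams.demo(self.kinetics)
            if self.demo_params
            else TransportParams.table_defaults(self.kinetics)
        )
        for name in ("D_vessel", "D_tissue", "P_vessel", "C_inlet"):
            v = getattr(self, name)
            if v is not None:
                setattr(base, name, v)
        tissue = base.reactions.get(im.TISSUE, ReactionSpec.none())
        R = self.R_max if self.R_max is not None else tissue.R_max
        K = self.K_M if self.K_M is not None else tissue.K_M
        kind = {"none": "none", "constant": "constant", "first-order": "first_order",
                "first_order": "first_order", "mm": "michaelis_menten",
                "michaelis_menten": "michaelis_menten"}[self.kinetics]
        if kind == "none":
            base.reactions[im.TISSUE] = ReactionSpec.none()
        elif kind == "constant":
            base.reactions[im.TISSUE] = ReactionSpec.constant(R)
        elif kind == "first_order":
            base.reactions[im.TISSUE] = ReactionSpec.first_order(R / K)
        else:
            base.reactions[im.TISSUE] = ReactionSpec.michaelis_menten(R, K)
        if self.organ_R_max is not None:
            base.reactions["organ"] = ReactionSpec.constant(self.organ_R_max) \
                if kind in ("constant", "none") else ReactionSpec.michaelis_menten(self.organ_R_max, K)
        return base

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as f:
            data = json.load(f)
        data["inlet_faces"] = tuple(data.get("inlet_faces", ("left", "right")))
        return cls(**data)


def _resolve_inputs(patterns: list[str]) -> list[str]:
    paths: list[str] = []
    for p in patterns:
        hits = sorted(globlib.glob(p))
        paths.extend(hits if hits else [p])
    return paths


def _load_mask(path: str, cfg: RunConfig) -> im.BinaryImage:
    gray = im.read_image(path, pixel_pitch=cfg.pixel_pitch)
    uniq = np.unique(gray.pixels)
    if len(uniq) <= 2:  # already a binary mask
        return im.BinaryImage(gray.pixels > 0, cfg.pixel_pitch)
    return im.binarize(gray, cfg.threshold)


def _render_heatmap(seg, mesh, sol, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import matplotlib.tri as mtri

    h, w = seg.shape
    pitch = seg.pixel_pitch
    tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    interp = mtri.LinearTriInterpolator(tri, np.nan_to_num(sol.C_full))
    xs = (np.arange(w) + 0.5) * pitch
    ys = (np.arange(h) + 0.5) * pitch
    xx, yy = np.meshgrid(xs, ys)
    grid = interp(xx, yy).filled(0.0)[::-1]
    fig, ax = plt.subplots(figsize=(5, 5 * h / w))
    imobj = ax.imshow(grid, cmap="inferno", vmin=0.0, vmax=1.0,
                      extent=[0, w * pitch, 0, h * pitch])
    fig.colorbar(imobj, ax=ax, label="C / C_inlet")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _render_arrows(mesh, sol, path: str, max_arrows: int = 1500) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cent = mesh.centroids()
    flux = sol.flux_per_element
    stride = max(1, len(cent) // max_arrows)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.quiver(cent[::stride, 0], cent[::stride, 1],
              flux[::stride, 0], flux[::stride, 1], angles="xy")
    ax.set_aspect("equal")
    ax.set_title("element flux vectors")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _render_contours(mesh, sol, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import matplotlib.tri as mtri

    tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    fig, ax = plt.subplots(figsize=(5, 5))
    cs = ax.tricontour(tri, np.nan_to_num(sol.C_full), levels=10, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="C / C_inlet")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def process_image(mask: im.BinaryImage, cfg: RunConfig, out: Path, stem: str) -> dict:
    """Segment, mesh, solve and report one image; writes artifacts under out/."""
    t0 = time.perf_counter()
    params = cfg.transport_params()
    seg = im.classify_domains(mask, cfg.inlet_faces)
    im.write_segmentation_png(seg, str(out / f"{stem}_segmentation.png"))
    im.write_labels_tiff(seg, str(out / f"{stem}_labels.tif"))

    mesh = mesh_segmented_image(
        seg,
        gradient_limit=cfg.gradient_limit,
        max_element_size=cfg.max_element_size_px * cfg.pixel_pitch,
    )
    write_msh2(mesh, str(out / f"{stem}_mesh.msh"))
    write_mesh_csv(mesh, str(out / f"{stem}_nodes.csv"), str(out / f"{stem}_elements.csv"))
    qual = MeshQualityReport.from_mesh(mesh)
    write_quality_report(qual, str(out / f"{stem}_quality.json"))
    log.info("%s: meshed %d nodes / %d elements (mean quality %.3f)",
             stem, mesh.n_nodes, mesh.n_triangles, qual.mean_quality)

    sol = solve_transport(mesh, params, tol=cfg.picard_tol, max_iter=cfg.picard_max_iter)
    for note in sol.notes:
        log.warning("%s: %s", stem, note)
    if not sol.converged:
        log.warning("%s: Picard iteration not converged", stem)

    # nodal field CSV
    import pandas as pd

    dom_of_node = np.zeros(mesh.n_nodes, dtype=int)
    dom_of_node[mesh.triangles.ravel()] = np.repeat(mesh.tri_domain, 3)
    pd.DataFrame({
        "node": np.arange(mesh.n_nodes),
        "x": mesh.nodes[:, 0],
        "y": mesh.nodes[:, 1],
        "domain": [mesh.domain_classes[d] for d in dom_of_node],
        "C": np.nan_to_num(sol.C_full),
    }).to_csv(out / f"{stem}_solution.csv", index=False)
    flux = sol.flux_per_element
    pd.DataFrame({
        "element": np.arange(mesh.n_triangles),
        "flux_x": flux[:, 0],
        "flux_y": flux[:, 1],
    }).to_csv(out / f"{stem}_flux.csv", index=False)

    if cfg.figures:
        _render_heatmap(seg, mesh, sol, str(out / f"{stem}_oxygen.png"))
        _render_arrows(mesh, sol, str(out / f"{stem}_flux_arrows.png"))
        _render_contours(mesh, sol, str(out / f"{stem}_contours.png"))

    report = compute_metrics(seg, mesh, sol, params)
    row = {"image": stem, **report.to_dict(),
           "mean_element_quality": qual.mean_quality,
           "runtime_s": time.perf_counter() - t0,
           "failed": False, "error": ""}
    with open(out / f"{stem}_metrics.json", "w") as f:
        json.dump(row, f, indent=2)
    return row


def run_pipeline(cfg: RunConfig) -> list[dict]:
    """Run the full pipeline on every input image; isolate per-image failures.

    Writes per-image artifacts, a batch metrics CSV and a config echo to
    the output directory; returns the metric rows.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_echo.json", "w") as f:
        json.dump(asdict(cfg), f, indent=2, default=list)

    paths = _resolve_inputs(list(cfg.inputs))
    if not paths:
        raise ValueError("no input images resolved from config.inputs")

    rows = []
    for path in paths:
        stem = Path(path).stem
        t0 = time.perf_counter()
        try:
            mask = _load_mask(path, cfg)
            rows.append(process_image(mask, cfg, out, stem))
        except Exception as exc:  # per-image isolation: batch continues
            log.error("%s failed: %s", stem, exc)
            log.debug("%s", traceback.format_exc())
            rows.append({"image": stem, "failed": True, "error": str(exc),
                         "runtime_s": time.perf_counter() - t0})

    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    return rows
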