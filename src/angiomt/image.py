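"""Image ingestion, binarization and domain segmentation.

A raw fluorescence image (endothelial stain, orthogonal projection) is
normalized to [0, 1], thresholded into a vessel mask, and the mask is
split into domains by connectivity to the designated oxygen-inlet faces
of the image:

* ``CONNECTED_VESSEL`` — vessel component touching at least one inlet face;
* ``DISCONNECTED_VESSEL`` — vessel "island" touching no inlet face;
* ``TISSUE`` — everything else (hydrogel / stroma);
* optional organ domains (e.g. an islet) carved out of tissue.

The N domains present are assigned evenly spaced gray levels i/(N-1),
tissue at 0 and connected vessel at 1, for rendering and for mesh-domain
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

TISSUE = "tissue"
DISCONNECTED_VESSEL = "disconnected_vessel"
CONNECTED_VESSEL = "connected_vessel"

#: image faces accepted as oxygen inlets
FACES = ("left", "right", "top", "bottom")

#: default physical pixel size: 1 um/pixel, so a 1000x1000 image is a 1x1 mm ROI
DEFAULT_PIXEL_PITCH = 1.0e-6

# 8-connectivity: diagonal single-pixel joins keep a vessel connected
_STRUCTURE8 = np.ones((3, 3), dtype=bool)


def _check_2d(pixels: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2D array, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"{name} must be at least 2x2, got shape {arr.shape}")
    return arr


@dataclass
class GrayImage:
    """Grayscale image with intensities normalized to [0, 1]."""

    pixels: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        self.pixels = _check_2d(self.pixels, "pixels").astype(float)
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            warnings.warn("intensities outside [0, 1]; clipping", stacklevel=2)
            self.pixels = np.clip(self.pixels, 0.0, 1.0)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryImage:
    """Boolean vessel mask (True = vessel)."""

    mask: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        self.mask = _check_2d(self.mask, "mask").astype(bool)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SegmentedImage:
    """Per-pixel domain classification.

    ``labels[i, j]`` indexes into ``domain_classes``, which is ordered by
    gray level: tissue first (level 0), organ domains, disconnected
    vessel, connected vessel last (level 1). ``gray_levels`` are the exact
    rationals i/(N-1); the familiar renderings 0.33/0.66 are rounded
    displays of 1/3 and 2/3.
    """

    labels: np.ndarray
    domain_classes: tuple[str, ...]
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    inlet_faces: tuple[str, ...] = ("left", "right")

    def __post_init__(self) -> None:
        self.labels = _check_2d(self.labels, "labels").astype(np.int32)
        self.domain_classes = tuple(self.domain_classes)
        if self.labels.max(initial=0) >= len(self.domain_classes):
            raise ValueError("label value outside domain_classes range")

    @property
    def n_domains(self) -> int:
        return len(self.domain_classes)

    @property
    def gray_levels(self) -> np.ndarray:
        n = self.n_domains
        if n == 1:
            return np.array([0.0])
        return np.arange(n) / (n - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_index(self, name: str) -> int:
        return self.domain_classes.index(name)

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == self.class_index(name)

    def vessel_mask(self) -> np.ndarray:
        """All vessel pixels, connected or not."""
        out = np.zeros(self.shape, dtype=bool)
        for name in (CONNECTED_VESSEL, DISCONNECTED_VESSEL):
            if name in self.domain_classes:
                out |= self.class_mask(name)
        return out

    def to_grayscale(self) -> np.ndarray:
        """Render the segmentation with its assigned gray levels."""
        return self.gray_levels[self.labels]


def normalize_intensities(raw: np.ndarray) -> np.ndarray:
    """Scale integer images by their dtype range; floats pass through."""
    raw = np.asarray(raw)
    if raw.dtype == np.uint8:
        return raw / 255.0
    if raw.dtype == np.uint16:
        return raw / 65535.0
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        return (raw.astype(float) - min(info.min, 0)) / info.max
    return raw.astype(float)


def binarize(image: GrayImage, threshold: float = 0.2) -> BinaryImage:
    """Threshold a normalized image into a vessel mask.

    Pixels with intensity >= ``threshold`` become vessel. The default 0.2
    separates stained endothelium from hydrogel background.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return BinaryImage(image.pixels >= threshold, image.pixel_pitch)


def _face_touch(mask: np.ndarray, labels: np.ndarray, faces: tuple[str, ...]) -> set[int]:
    """Component ids (from ndimage.label) that touch any of the given faces."""
    touching: set[int] = set()
    slices = {
        "left": (slice(None), 0),
        "right": (slice(None), -1),
        "top": (0, slice(None)),
        "bottom": (-1, slice(None)),
    }
    for face in faces:
        edge = labels[slices[face]]
        touching.update(int(v) for v in np.unique(edge) if v != 0)
    return touching


def classify_domains(
    mask: BinaryImage, inlet_faces: tuple[str, ...] = ("left", "right")
) -> SegmentedImage:
    """Split a vessel mask into connected / disconnected vessel and tissue.

    8-connected vessel components touching at least one inlet face are
    classified ``CONNECTED_VESSEL`` (they will receive the inlet oxygen
    Dirichlet condition); the rest are ``DISCONNECTED_VESSEL`` islands;
    background is ``TISSUE``. Only classes actually present appear in the
    result, so an image with islands yields N=3 gray levels [0, 0.5, 1].
    """
    inlet_faces = tuple(inlet_faces)
    if not inlet_faces or any(f not in FACES for f in inlet_faces):
        raise ValueError(f"inlet_faces must be a nonempty subset of {FACES}")

    comp, n_comp = ndimage.label(mask.mask, structure=_STRUCTURE8)
    if n_comp == 0:
        warnings.warn(
            "mask contains no vessel pixels; segmentation has a single "
            "tissue class and cannot be solved",
            stacklevel=2,
        )
        return SegmentedImage(
            np.zeros(mask.shape, dtype=np.int32), (TISSUE,), mask.pixel_pitch, inlet_faces
        )

    connected_ids = _face_touch(mask.mask, comp, inlet_faces)
    connected = np.isin(comp, sorted(connected_ids)) if connected_ids else np.zeros(mask.shape, bool)
    disconnected = mask.mask & ~connected

    classes = [TISSUE]
    if disconnected.any():
        classes.append(DISCONNECTED_VESSEL)
    if connected.any():
        classes.append(CONNECTED_VESSEL)

    labels = np.zeros(mask.shape, dtype=np.int32)
    if disconnected.any():
        labels[disconnected] = classes.index(DISCONNECTED_VESSEL)
    if connected.any():
        labels[connected] = classes.index(CONNECTED_VESSEL)
    return SegmentedImage(labels, tuple(classes), mask.pixel_pitch, inlet_faces)


def add_organ_region(
    seg: SegmentedImage, organ_mask: np.ndarray, kinetics_tag: str = "organ"
) -> SegmentedImage:
    """Carve an organ domain (e.g. an islet) out of the tissue background.

    Organ pixels may only overwrite tissue: vessel pixels win, so a mask
    overlapping vessels is silently clipped to its tissue part. N grows by
    one and gray levels re-space to i/(N-1), e.g. [0, 1/3, 2/3, 1].
    """
    organ_mask = _check_2d(organ_mask, "organ_mask").astype(bool)
    if organ_mask.shape != seg.shape:
        raise ValueError("organ_mask shape does not match segmentation")
    if not organ_mask.any():
        return seg
    organ_name = f"organ:{kinetics_tag}"
    if organ_name in seg.domain_classes:
        raise ValueError(f"organ domain {kinetics_tag!r} already present")

    tissue_part = organ_mask & seg.class_mask(TISSUE)
    if not tissue_part.any():
        raise ValueError("organ mask overlaps only vessel pixels; organ domain would be empty")

    # organ slots in just after tissue so connected vessel keeps level 1
    classes = [TISSUE, organ_name] + [c for c in seg.domain_classes if c != TISSUE]
    remap = np.array([classes.index(c) for c in seg.domain_classes], dtype=np.int32)
    labels = remap[seg.labels]
    labels[tissue_part] = classes.index(organ_name)
    return SegmentedImage(labels, tuple(classes), seg.pixel_pitch, seg.inlet_faces)


# ---------------------------------------------------------------------------
# readers / writers


def read_image(
    path: str, pixel_pitch: float = DEFAULT_PIXEL_PITCH, channel: int | None = None
) -> GrayImage:
    """Read a TIFF or PNG image as a normalized grayscale image.

    Multi-channel images require an explicit ``channel`` index.
    """
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if channel is None:
            raise ValueError(
                f"image has {raw.shape[-1] if raw.shape[-1] < 5 else raw.shape[0]} "
                "channels; pass channel= to select one"
            )
        raw = raw[..., channel] if raw.shape[-1] < 5 else raw[channel]
    return GrayImage(normalize_intensities(raw), pixel_pitch)


def write_mask_png(mask: BinaryImage, path: str) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def read_mask_png(path: str, pixel_pitch: float = DEFAULT_PIXEL_PITCH) -> BinaryImage:
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(str(path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return BinaryImage(raw > 0, pixel_pitch)


def write_segmentation_png(seg: SegmentedImage, path: str) -> None:
    """Write the segmentation as an 8-bit grayscale rendering."""
    import imageio.v3 as iio

    gray = np.round(seg.to_grayscale() * 255).astype(np.uint8)
    iio.imwrite(str(path), gray)


def write_labels_tiff(seg: SegmentedImage, path: str) -> None:
    import tifffile

    tifffile.imwrite(str(path), seg.labels.astype(np.int32))
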