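"""Binarization, domain classification and gray-level assignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from angiomt.image import (
    CONNECTED_VESSEL,
    DISCONNECTED_VESSEL,
    TISSUE,
    BinaryImage,
    GrayImage,
    add_organ_region,
    binarize,
    classify_domains,
    normalize_intensities,
    read_mask_png,
    write_mask_png,
)


class TestBinarize:
    def test_uniform_above_threshold_all_vessel(self):
        img = GrayImage(np.full((8, 8), 0.5))
        assert binarize(img, 0.2).mask.all()

    def test_uniform_zero_all_background(self):
        img = GrayImage(np.zeros((8, 8)))
        assert not binarize(img, 0.2).mask.any()

    def test_checkerboard_matches_pixelwise_comparison(self):
        vals = np.indices((10, 10)).sum(axis=0) % 2
        img = GrayImage(np.where(vals == 1, 0.9, 0.1))
        assert np.array_equal(binarize(img, 0.2).mask, vals == 1)

    @given(
        hnp.arrays(float, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
                   elements=st.floats(0, 1)),
        st.floats(0.05, 0.95),
    )
    def test_matches_elementwise_oracle(self, pixels, threshold):
        got = binarize(GrayImage(pixels), threshold).mask
        assert np.array_equal(got, np.asarray(pixels) >= threshold)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.5, 2.0])
    def test_rejects_bad_threshold(self, threshold):
        with pytest.raises(ValueError, match="threshold"):
            binarize(GrayImage(np.zeros((4, 4))), threshold)

    def test_rejects_non_2d_and_tiny_input(self):
        with pytest.raises(ValueError, match="2D"):
            GrayImage(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError, match="at least 2x2"):
            GrayImage(np.zeros((1, 5)))


def _flood_fill_oracle(mask, inlet_faces):
    """8-connected BFS from inlet-face vessel pixels (independent oracle)."""
    h, w = mask.shape
    seeds = []
    if "left" in inlet_faces:
        seeds += [(i, 0) for i in range(h)]
    if "right" in inlet_faces:
        seeds += [(i, w - 1) for i in range(h)]
    if "top" in inlet_faces:
        seeds += [(0, j) for j in range(w)]
    if "bottom" in inlet_faces:
        seeds += [(h - 1, j) for j in range(w)]
    seen = np.zeros_like(mask)
    stack = [s for s in seeds if mask[s]]
    for s in stack:
        seen[s] = True
    while stack:
        i, j = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                    seen[ni, nj] = True
                    stack.append((ni, nj))
    return seen


class TestClassifyDomains:
    def test_vertical_bar_missing_inlets_is_disconnected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:, 8:12] = True  # spans top-bottom, not left-right
        seg = classify_domains(BinaryImage(mask), ("left", "right"))
        assert CONNECTED_VESSEL not in seg.domain_classes
        assert np.array_equal(seg.class_mask(DISCONNECTED_VESSEL), mask)

    def test_horizontal_bar_is_connected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[8:12, :] = True
        seg = classify_domains(BinaryImage(mask))
        assert np.array_equal(seg.class_mask(CONNECTED_VESSEL), mask)

    def test_bar_plus_island_has_three_gray_levels(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[8:12, :] = True
        mask[2:4, 5:8] = True
        seg = classify_domains(BinaryImage(mask))
        assert seg.domain_classes == (TISSUE, DISCONNECTED_VESSEL, CONNECTED_VESSEL)
        assert np.array_equal(seg.gray_levels, [0.0, 0.5, 1.0])

    def test_empty_mask_single_class_with_warning(self):
        with pytest.warns(UserWarning, match="no vessel"):
            seg = classify_domains(BinaryImage(np.zeros((8, 8), dtype=bool)))
        assert seg.domain_classes == (TISSUE,)

    def test_rejects_bad_inlet_faces(self):
        with pytest.raises(ValueError, match="inlet_faces"):
            classify_domains(BinaryImage(np.ones((4, 4), dtype=bool)), ())
        with pytest.raises(ValueError, match="inlet_faces"):
            classify_domains(BinaryImage(np.ones((4, 4), dtype=bool)), ("north",))

    @pytest.mark.parametrize("seed", range(5))
    def test_split_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) < 0.35
        faces = [("left", "right"), ("left",), ("top", "bottom")][seed % 3]
        seg = classify_domains(BinaryImage(mask), faces)
        connected = _flood_fill_oracle(mask, faces)
        got = (
            seg.class_mask(CONNECTED_VESSEL)
            if CONNECTED_VESSEL in seg.domain_classes
            else np.zeros_like(mask)
        )
        assert np.array_equal(got, connected)

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_every_pixel_exactly_one_class(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((24, 24)) < 0.3
        seg = classify_domains(BinaryImage(mask))
        counts = sum(int(seg.class_mask(c).sum()) for c in seg.domain_classes)
        assert counts == mask.size

    def test_gray_level_spacing_exact(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[6:9, :] = True
        mask[1:3, 4:6] = True
        seg = classify_domains(BinaryImage(mask))
        spacings = np.diff(seg.gray_levels)
        assert np.all(spacings == 1.0 / (seg.n_domains - 1))


class TestAddOrganRegion:
    @pytest.fixture
    def seg3(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[12:17, :] = True
        mask[2:5, 3:6] = True
        return classify_domains(BinaryImage(mask))

    def test_four_classes_respace_to_thirds(self, seg3):
        organ = np.zeros((30, 30), dtype=bool)
        organ[22:28, 22:28] = True
        seg4 = add_organ_region(seg3, organ, "islet")
        assert seg4.n_domains == 4
        assert np.allclose(seg4.gray_levels, [0, 1 / 3, 2 / 3, 1])
        assert seg4.domain_classes[-1] == CONNECTED_VESSEL  # vessel keeps level 1

    def test_empty_mask_is_noop(self, seg3):
        assert add_organ_region(seg3, np.zeros((30, 30), dtype=bool)) is seg3

    def test_organ_fully_inside_vessel_rejected(self, seg3):
        organ = np.zeros((30, 30), dtype=bool)
        organ[13:16, 5:10] = True  # entirely within the connected bar
        with pytest.raises(ValueError, match="organ"):
            add_organ_region(seg3, organ)

    def test_vessel_pixels_win_on_overlap(self, seg3):
        organ = np.zeros((30, 30), dtype=bool)
        organ[10:20, 2:8] = True  # straddles the bar
        seg4 = add_organ_region(seg3, organ, "islet")
        bar = seg3.class_mask(CONNECTED_VESSEL)
        assert np.array_equal(seg4.class_mask(CONNECTED_VESSEL), bar)
        assert np.array_equal(seg4.class_mask("organ:islet"), organ & ~bar)


class TestIntensityNormalization:
    def test_uint8_and_uint16_scales(self):
        assert normalize_intensities(np.array([[255, 0]], dtype=np.uint8)).max() == 1.0
        assert normalize_intensities(np.array([[65535, 0]], dtype=np.uint16)).max() == 1.0

    def test_out_of_range_float_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            img = GrayImage(np.array([[1.5, -0.2], [0.5, 0.5]]))
        assert img.pixels.max() <= 1.0 and img.pixels.min() >= 0.0


def test_mask_png_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    mask = BinaryImage(rng.random((40, 40)) < 0.3, 5e-6)
    path = tmp_path / "m.png"
    write_mask_png(mask, str(path))
    back = read_mask_png(str(path), 5e-6)
    assert np.array_equal(back.mask, mask.mask)


def test_tiff_reader_round_trip(tmp_path):
    import tifffile

    from angiomt.image import read_image

    raw = (np.random.default_rng(1).random((20, 20)) * 65535).astype(np.uint16)
    path = tmp_path / "img.tif"
    tifffile.imwrite(str(path), raw)
    img = read_image(str(path))
    assert np.allclose(img.pixels, raw / 65535.0)
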