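"""Image stage: channel choice, rotation, cropping, grid fit, quantification."""

import numpy as np
import pytest
from PIL import Image

from colonyscreen import (
    FORMATS,
    GridFitError,
    PlateImage,
    analyze_image,
    crop_plate,
    estimate_rotation,
    fit_grid,
    quantify_colonies,
    render_plate_image,
    select_channel,
)
from colonyscreen.image import _apply_rotation


def _disc_image(radius, shape=(64, 64), center=None, agar=120.0, colony=220.0):
    img = np.full(shape, agar)
    cy, cx = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = colony
    return img


class TestSelectChannel:
    def test_grayscale_returns_zero(self):
        assert select_channel(PlateImage(_disc_image(8))) == 0

    def test_channel_with_colonies_wins(self):
        disc = _disc_image(8)
        for lead in range(3):
            channels = [np.full_like(disc, 120.0)] * 3
            channels = [disc if i == lead else ch for i, ch in enumerate(channels)]
            rgb = np.stack(channels, axis=2)
            # oracle: the channel with the largest intensity std
            oracle = int(np.argmax([np.std(rgb[:, :, i]) for i in range(3)]))
            assert select_channel(PlateImage(rgb)) == oracle == lead

    def test_identical_channels_tie_break_to_lowest(self):
        disc = _disc_image(8)
        rgb = np.stack([disc, disc, disc], axis=2)
        assert select_channel(PlateImage(rgb)) == 0


class TestEstimateRotation:
    def test_aligned_plate_needs_no_correction(self, rendered_384):
        _, _, image, _ = rendered_384
        assert abs(estimate_rotation(PlateImage(image))) <= 0.1

    @pytest.mark.parametrize("angle", [2.0, -3.0])
    def test_rendered_skew_recovered(self, rendered_384, angle):
        fmt, sizes, _, _ = rendered_384
        image, _ = render_plate_image(sizes, fmt, spacing=16, rotation=angle)
        correction = estimate_rotation(PlateImage(image))
        assert correction == pytest.approx(-angle, abs=0.2)

    def test_blank_agar_warns_and_returns_zero(self):
        blank = PlateImage(np.full((100, 150), 120.0))
        with pytest.warns(UserWarning, match="foreground"):
            assert estimate_rotation(blank) == 0.0


class TestCropPlate:
    def test_none_is_identity(self, rendered_384):
        _, _, image, _ = rendered_384
        out, offset = crop_plate(PlateImage(image), "none")
        assert offset == (0, 0)
        np.testing.assert_array_equal(out.pixels, PlateImage(image).pixels)

    def test_fixed_margin_arithmetic(self):
        img = PlateImage(np.zeros((600, 1000)))
        out, offset = crop_plate(img, "fixed_margin", margin=0.05)
        assert out.pixels.shape[:2] == (540, 900)
        assert offset == (30, 50)

    def test_auto_crop_recovers_agar_bounds(self, rendered_384):
        fmt, sizes, _, _ = rendered_384
        border = 40
        image, truth = render_plate_image(sizes, fmt, spacing=16, border_px=border)
        out, (oy, ox) = crop_plate(PlateImage(image), "auto")
        assert abs(oy - border) <= 5 and abs(ox - border) <= 5
        h, w = out.pixels.shape[:2]
        assert abs(image.shape[0] - 2 * border - h) <= 10
        assert abs(image.shape[1] - 2 * border - w) <= 10

    def test_auto_without_usable_split_falls_back(self):
        flat = PlateImage(np.full((200, 300), 120.0))
        with pytest.warns(UserWarning, match="falling back"):
            out, offset = crop_plate(flat, "auto")
        assert offset == (10, 15)  # the fixed 5% margins


class TestFitGrid:
    def test_centers_recovered_subpixel(self, rendered_384):
        fmt, _, image, truth = rendered_384
        grid = fit_grid(PlateImage(image), fmt)
        assert np.abs(grid.row_centers - truth["row_centers"]).max() < 0.5
        assert np.abs(grid.col_centers - truth["col_centers"]).max() < 0.5

    def test_96_plate_has_8_rows_12_columns(self, rng):
        fmt = FORMATS[96]
        sizes = rng.uniform(60, 150, fmt.physical_shape)
        image, _ = render_plate_image(sizes, fmt, spacing=16)
        grid = fit_grid(PlateImage(image), fmt)
        assert len(grid.row_centers) == 8 and len(grid.col_centers) == 12

    def test_blank_image_fails_naming_an_axis(self):
        with pytest.raises(GridFitError, match="row|column"):
            fit_grid(PlateImage(np.full((300, 450), 120.0)), FORMATS[96])

    def test_missing_colonies_tolerated(self, rng):
        fmt = FORMATS[96]
        sizes = rng.uniform(60, 150, fmt.physical_shape)
        sizes[2, :] = 0.0  # one empty row
        sizes[:, 5] = 0.0  # one empty column
        image, truth = render_plate_image(sizes, fmt, spacing=16)
        grid = fit_grid(PlateImage(image), fmt)
        assert np.abs(grid.row_centers - truth["row_centers"]).max() < 0.5


class TestQuantifyColonies:
    def test_centered_disc_size_and_circularity(self, rng):
        fmt = FORMATS[96]
        sizes = np.full(fmt.physical_shape, np.pi * 10 ** 2)
        image, truth = render_plate_image(sizes, fmt, spacing=24)
        grid = fit_grid(PlateImage(image), fmt)
        plate = quantify_colonies(PlateImage(image), grid, fmt)
        assert np.nanmax(np.abs(plate.sizes - np.pi * 100) / (np.pi * 100)) <= 0.05
        assert np.nanmin(plate.circularity) >= 0.9

    def test_empty_node_has_zero_size_no_circularity(self, rng):
        fmt = FORMATS[96]
        sizes = rng.uniform(100, 150, fmt.physical_shape)
        sizes[3, 4] = 0.0
        image, _ = render_plate_image(sizes, fmt, spacing=16)
        grid = fit_grid(PlateImage(image), fmt)
        plate = quantify_colonies(PlateImage(image), grid, fmt)
        assert plate.sizes[3, 4] == 0
        assert np.isnan(plate.circularity[3, 4])

    @pytest.mark.parametrize("count", [96, 384, 768, 1536])
    def test_every_format_yields_exact_record_count(self, rng, count):
        fmt = FORMATS[count]
        sizes = rng.uniform(60, 150, fmt.physical_shape)
        image, truth = render_plate_image(sizes, fmt, spacing=16)
        grid = fit_grid(PlateImage(image), fmt)
        plate = quantify_colonies(PlateImage(image), grid, fmt)
        assert sum(1 for _ in plate.measurements()) == count
        occ = fmt.occupied_mask()
        rel = np.abs(plate.sizes[occ] - truth["drawn_area"][occ]) / truth["drawn_area"][occ]
        assert rel.max() <= 0.05

    def test_sizes_increase_with_disc_radius(self):
        # radii 3..15 px, each rendered at several nodes; the mean
        # quantified size per radius must be strictly increasing
        fmt = FORMATS[96]
        radii = np.tile(np.arange(3.0, 15.1, 1.0), 8)[:96]
        sizes = (np.pi * radii ** 2).reshape(fmt.physical_shape)
        image, _ = render_plate_image(sizes, fmt, spacing=32)
        grid = fit_grid(PlateImage(image), fmt)
        plate = quantify_colonies(PlateImage(image), grid, fmt)
        means = [plate.sizes.ravel()[radii == r].mean() for r in np.arange(3.0, 15.1)]
        assert (np.diff(means) > 0).all()

    def test_assignment_never_double_counts(self, rendered_384):
        fmt, _, image, _ = rendered_384
        pi = PlateImage(image)
        grid = fit_grid(pi, fmt)
        plate = quantify_colonies(pi, grid, fmt)
        foreground_total = int((image > 170).sum())
        assert np.nansum(plate.sizes) <= foreground_total

    def test_quantification_invariant_to_small_rotation(self, rendered_384):
        fmt, sizes, image0, truth = rendered_384
        pi0 = PlateImage(image0)
        base = quantify_colonies(pi0, fit_grid(pi0, fmt), fmt)
        rotated, _ = render_plate_image(sizes, fmt, spacing=16, rotation=3.0)
        pi = _apply_rotation(PlateImage(rotated),
                             estimate_rotation(PlateImage(rotated)))
        recovered = quantify_colonies(pi, fit_grid(pi, fmt), fmt)
        rel = np.abs(recovered.sizes - base.sizes) / np.maximum(base.sizes, 1)
        assert np.nanmax(rel) <= 0.05

    def test_quantification_invariant_to_crop_choice_without_border(self, rendered_384):
        fmt, _, image, _ = rendered_384
        results = {}
        for method in ("auto", "none"):
            cropped, _ = crop_plate(PlateImage(image), method)
            grid = fit_grid(cropped, fmt)
            results[method] = quantify_colonies(cropped, grid, fmt).sizes
        rel = np.abs(results["auto"] - results["none"]) / np.maximum(results["none"], 1)
        assert np.nanmax(rel) <= 0.05


class TestAnalyzeImage:
    def _save(self, image, path, dpi=(200, 200)):
        Image.fromarray(image.astype(np.uint8)).save(path, dpi=dpi)

    def test_end_to_end_writes_dat_with_all_rows(self, tmp_path, rendered_384):
        fmt, _, image, _ = rendered_384
        path = tmp_path / "x_dm_G1_1_a.png"
        self._save(image, path)
        plate = analyze_image(str(path), fmt, out_dir=str(tmp_path))
        dat = tmp_path / plate.plate_id
        assert dat.exists()
        assert sum(1 for _ in open(dat)) == 384

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "x_dm_G1_1_a.png"
        bad.write_text("not an image")
        with pytest.raises(Exception):
            analyze_image(str(bad), FORMATS[96])

    def test_low_resolution_warns(self, tmp_path, rendered_384):
        fmt, _, image, _ = rendered_384
        path = tmp_path / "x_dm_G1_1_a.png"
        self._save(image, path, dpi=(72, 72))
        with pytest.warns(UserWarning, match="dpi"):
            analyze_image(str(path), fmt)
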