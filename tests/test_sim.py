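import numpy as np
import pytest
from scipy.optimize import curve_fit

from smdol.registration import AffineTransform2D
from smdol.sim import (
    CameraModel,
    Photophysics,
    REFERENCE_PHOTOPHYSICS,
    SimConfig,
    make_cell_region,
    place_probes,
    render_channel,
    simulate_experiment,
)

from conftest import make_ground_truth


class TestPhotophysics:
    def test_duty_cycle_from_dwell_times(self):
        pp = Photophysics()  # on 0.025, off 0.01
        assert pp.duty_cycle == pytest.approx(0.025 / 0.035)

    @pytest.mark.parametrize(
        "kwargs", [dict(on_time=0.0), dict(bleach_constant=1.0), dict(photons_per_s=-1.0), dict(labels_per_epitope=0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Photophysics(**kwargs)


class TestMakeCellRegion:
    def test_full_frame_limit(self):
        mask = make_cell_region((64, 64), 1.0, seed=0)
        assert mask.all()

    def test_deterministic(self):
        a = make_cell_region((128, 128), 0.4, seed=5)
        b = make_cell_region((128, 128), 0.4, seed=5)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_area_fraction_within_20pct(self, seed):
        mask = make_cell_region((256, 256), 0.4, seed=seed)
        frac = mask.sum() / mask.size
        assert 0.32 <= frac <= 0.48

    def test_single_connected_region_no_holes(self):
        from scipy import ndimage

        mask = make_cell_region((128, 128), 0.3, seed=7)
        _, n = ndimage.label(mask)
        assert n == 1
        assert np.array_equal(ndimage.binary_fill_holes(mask), mask)

    def test_degenerate_frame_rejected(self):
        with pytest.raises(ValueError):
            make_cell_region((8, 256), 0.5, seed=0)


class TestPlaceProbes:
    def test_dol_one_labels_everything(self):
        mask = make_cell_region((128, 128), 0.5, seed=0)
        gt = place_probes(mask, 0.3, 1.0, 0.0, 160.0, seed=1)
        assert gt.probes["has_target"].all()

    def test_dol_zero_no_unspecific_gives_empty_target(self):
        mask = make_cell_region((128, 128), 0.5, seed=0)
        gt = place_probes(mask, 0.3, 0.0, 0.0, 160.0, seed=1)
        assert len(gt.channel_positions("target")) == 0

    def test_poisson_probe_count(self):
        # density 0.2/um^2 over ~500 um^2 -> mean 100, 3 sigma = 30
        mask = np.zeros((200, 200), dtype=bool)
        mask[:125, :] = True  # 125*200 px * (0.16 um)^2 = 640 um^2
        area = mask.sum() * 0.16**2
        gt = place_probes(mask, 0.2, 0.5, 0.0, 160.0, seed=2)
        mean = 0.2 * area
        assert abs(len(gt.probes) - mean) <= 3 * np.sqrt(mean)

    def test_probes_inside_mask(self):
        mask = make_cell_region((128, 128), 0.3, seed=3)
        gt = place_probes(mask, 0.5, 0.5, 0.0, 160.0, seed=4)
        c = np.floor(gt.probes["x_nm"] / 160.0).astype(int)
        r = np.floor(gt.probes["y_nm"] / 160.0).astype(int)
        assert mask[r, c].all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            place_probes(np.zeros((64, 64), bool), 0.1, 0.5, 0.0, 160.0, seed=0)

    def test_labeled_fraction_converges(self):
        mask = np.ones((256, 256), dtype=bool)
        gt = place_probes(mask, 1.0, 0.3, 0.0, 160.0, seed=5)
        n = len(gt.probes)
        assert n >= 500
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(gt.probes["has_target"].mean() - 0.3) <= 4 * se


class TestRenderChannel:
    def test_background_only_mean(self):
        gt = make_ground_truth([], frame_size_px=(64, 64))
        cam = CameraModel(gain=1.0, offset=100.0, read_noise=0.0)
        img = render_channel(
            gt, "reference", REFERENCE_PHOTOPHYSICS, cam, 160.0, 10, background_level=6.0, seed=0
        )
        expected = 100.0 + 6.0
        sem = np.sqrt(6.0 / 10) / np.sqrt(64 * 64)
        assert abs(img.pixels.mean() - expected) <= 3 * sem

    def test_rendered_spot_width_recovers_psf_sigma(self, quiet_camera):
        px = quiet_camera.pixel_size_nm
        gt = make_ground_truth([(32.3 * px, 31.8 * px)], frame_size_px=(64, 64))
        img = render_channel(
            gt, "reference", REFERENCE_PHOTOPHYSICS, quiet_camera, 150.0, 20, 2.0, seed=1
        )
        yy, xx = np.mgrid[0:64, 0:64]

        def model(xy, a, x0, y0, s, b):
            x, y = xy
            return (a * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * s**2)) + b).ravel()

        p0 = (img.pixels.max() - img.pixels.min(), 32, 32, 1.0, img.pixels.min())
        popt, _ = curve_fit(
            model, ((xx + 0.5).ravel(), (yy + 0.5).ravel()), img.pixels.ravel(), p0=p0
        )
        fitted_sigma_nm = abs(popt[3]) * px
        # the point-sampled refit sees the PSF broadened by pixel
        # integration: sigma_eff^2 = sigma^2 + px^2/12
        expected = np.sqrt(150.0**2 + px**2 / 12.0)
        assert abs(fitted_sigma_nm - expected) / expected < 0.05

    def test_duty_cycle_visibility_fraction(self):
        # on 0.025 / off 0.01 -> per-frame visibility 0.714 of unbleached
        pp = Photophysics(bleach_constant=0.0)
        rng_frames = 400
        gt = make_ground_truth(
            [(k * 600.0, 5000.0) for k in range(3, 14)], frame_size_px=(64, 64)
        )
        cam = CameraModel(read_noise=0.0)
        # tally frame states through the photon budget: mean image signal
        # above background is proportional to mean visibility
        img_blinking = render_channel(gt, "reference", pp, cam, 150.0, rng_frames, 0.0, seed=3)
        img_steady = render_channel(
            gt, "reference", REFERENCE_PHOTOPHYSICS, cam, 150.0, rng_frames, 0.0, seed=4
        )
        ratio = (img_blinking.pixels.mean() - cam.offset) / (
            img_steady.pixels.mean() - cam.offset
        )
        assert ratio == pytest.approx(0.025 / 0.035, abs=0.03)

    def test_photon_budget(self):
        gt = make_ground_truth(
            [(k * 800.0, j * 800.0) for k in range(2, 11) for j in range(2, 11)],
            frame_size_px=(64, 64),
        )
        cam = CameraModel(gain=1.0, offset=0.0, read_noise=0.0, qe=0.9)
        n_frames = 5
        img = render_channel(
            gt, "reference", REFERENCE_PHOTOPHYSICS, cam, 150.0, n_frames, 0.0, seed=5
        )
        total = img.pixels.sum() * n_frames  # sum over all averaged frames
        expected = len(gt.probes) * 0.9 * 350.0 * n_frames
        assert abs(total - expected) <= 5 * np.sqrt(expected)

    def test_deterministic_under_seed(self, quiet_camera):
        gt = make_ground_truth([(3000.0, 3000.0)], frame_size_px=(32, 32))
        kwargs = dict(
            ground_truth=gt,
            channel="reference",
            photophysics=REFERENCE_PHOTOPHYSICS,
            camera=quiet_camera,
            psf_sigma_nm=150.0,
            n_frames=5,
            background_level=3.0,
            seed=42,
        )
        assert np.array_equal(render_channel(**kwargs).pixels, render_channel(**kwargs).pixels)


class TestSimulateExperiment:
    def test_identity_transform_coincident_channels(self, sim_config):
        cfg = sim_config.replace(
            chromatic_shift_x_nm=0.0,
            chromatic_shift_y_nm=0.0,
            chromatic_rotation_deg=0.0,
            chromatic_scale=1.0,
            unspec_density_um2=0.0,
        )
        cells = simulate_experiment(cfg, 1, seed=0)
        gt = cells[0].ground_truth
        tagged = gt.probes[gt.probes["has_target"]]
        target_xy = gt.channel_positions("target")
        assert np.allclose(target_xy, tagged[["x_nm", "y_nm"]].to_numpy())

    def test_distinct_ground_truths(self, sim_config):
        cells = simulate_experiment(sim_config, 5, seed=9)
        assert len(cells) == 5
        counts = {len(c.ground_truth.probes) for c in cells}
        positions = {tuple(np.round(c.ground_truth.probes["x_nm"].head(3), 3)) for c in cells}
        assert len(positions) == 5 or len(counts) > 1

    def test_translation_only_chromatic_displacement(self, sim_config):
        cfg = sim_config.replace(
            chromatic_shift_x_nm=120.0,
            chromatic_shift_y_nm=80.0,
            chromatic_rotation_deg=0.0,
            chromatic_scale=1.0,
            unspec_density_um2=0.0,
            true_dol=1.0,
        )
        cells = simulate_experiment(cfg, 2, seed=3)
        for cell in cells:
            gt = cell.ground_truth
            true_xy = gt.probes[["x_nm", "y_nm"]].to_numpy()
            shifted = gt.channel_positions("target")
            disp = shifted - true_xy
            assert np.allclose(disp.mean(axis=0), (120.0, 80.0), atol=1e-9)
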