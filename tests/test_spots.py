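"""Spot detection, densities, and time-series utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smolsensor import simulate as sim
from smolsensor import spots as sp
from smolsensor.kinetics import TimeCourse

from conftest import match_detections


def snr10_intensity(scene):
    """Integrated intensity whose peak amplitude is 10x the background noise."""
    noise_sd = np.sqrt(scene.background * scene.photon_scale + scene.read_noise_sd**2)
    s_px = scene.psf_sigma / scene.pixel_size
    return 10 * noise_sd * 2 * np.pi * s_px**2


class TestDetectSpots:
    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            sp.detect_spots(np.zeros((4, 4, 4)), pixel_size=0.1)

    def test_blank_frames_rarely_trigger(self, scene):
        fp = []
        for s in range(20):
            img = sim.render_tirf_frame(np.empty((0, 2)), np.empty(0), scene, seed=s)
            fp.append(len(sp.detect_spots(img, scene.pixel_size, min_snr=5,
                                          psf_sigma=scene.psf_sigma)))
        assert np.mean(fp) <= 1.0  # per 100 um^2 FOV

    def test_recall_and_localization_at_snr10(self, scene):
        intensity = snr10_intensity(scene)
        matched, rms = 0, []
        for s in range(5):
            pos = sim.gen_spot_positions(25, scene, seed=s, min_separation=3 * scene.psf_sigma)
            img = sim.render_tirf_frame(pos, np.full(25, intensity), scene, seed=100 + s)
            tab = sp.detect_spots(img, scene.pixel_size, min_snr=5, psf_sigma=scene.psf_sigma)
            m, r = match_detections(tab, pos, 2 * scene.pixel_size)
            matched += m
            rms.append(r)
        assert matched >= 0.96 * 125
        assert np.mean(rms) < 0.5 * scene.pixel_size

    def test_pair_at_six_sigma_resolved(self, scene):
        mid = scene.fov_size[0] / 2
        gap = 6 * scene.psf_sigma
        pos = np.array([[mid - gap / 2, mid], [mid + gap / 2, mid]])
        img = sim.render_tirf_frame(pos, [2000.0, 2000.0], scene, seed=0)
        tab = sp.detect_spots(img, scene.pixel_size, min_snr=5, psf_sigma=scene.psf_sigma)
        m, _ = match_detections(tab, pos, 2 * scene.pixel_size)
        assert m == 2

    def test_intensity_estimates_unbiased(self, scene):
        """Fitted integrated intensity matches the rendered ground truth."""
        pos = sim.gen_spot_positions(15, scene, seed=3, min_separation=4 * scene.psf_sigma)
        truth = sim.gen_monomer_intensities(15, seed=4)
        img = sim.render_tirf_frame(pos, truth, scene, seed=5)
        tab = sp.detect_spots(img, scene.pixel_size, min_snr=5, psf_sigma=scene.psf_sigma)
        ratios = []
        for x, y, i_true in zip(pos[:, 0], pos[:, 1], truth):
            d = np.hypot(tab["x"] - x, tab["y"] - y)
            if d.min() < 2 * scene.pixel_size:
                ratios.append(tab["intensity"][d.idxmin()] / i_true)
        assert len(ratios) >= 13
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestSpotDensity:
    def test_definition(self):
        tab = pd.DataFrame({"frame": [0] * 25, "x": 0.0, "y": 0.0, "intensity": 1.0})
        assert sp.spot_density(tab, roi_area=100.0) == 25.0

    def test_cell_footprint_inversion(self):
        tab = pd.DataFrame({"frame": [0] * 375, "x": 0.0, "y": 0.0, "intensity": 1.0})
        assert sp.spot_density(tab, roi_area=1500.0) == pytest.approx(25.0)

    def test_empty_table_and_bad_area(self):
        empty = pd.DataFrame(columns=["frame", "x", "y", "intensity"])
        assert sp.spot_density(empty, roi_area=100.0) == 0.0
        with pytest.raises(ValueError):
            sp.spot_density(empty, roi_area=0.0)

    def test_per_frame_includes_empty_frames(self):
        tab = pd.DataFrame({"frame": [0, 0, 2], "x": 0.0, "y": 0.0, "intensity": 1.0})
        d = sp.spot_density(tab, roi_area=100.0, per_frame=True, n_frames=4)
        assert d["density"].tolist() == [2.0, 0.0, 1.0, 0.0]

    def test_photobleaching_decline(self, scene, monomer_model):
        """With bleaching and no arrivals, measured density trends downward."""
        spec = sim.SceneSpec(bleach_prob_per_frame=0.08)
        early, late = [], []
        for s in range(3):
            stack, _ = sim.render_movie(spec, monomer_model, 12, seed=s, bleach=True,
                                        min_separation=3 * spec.psf_sigma)
            tab = sp.detect_spots_stack(stack, spec.pixel_size, min_snr=5,
                                        psf_sigma=spec.psf_sigma)
            d = sp.spot_density(tab, spec.area_um2, per_frame=True, n_frames=12)["density"]
            early.append(d[:4].mean())
            late.append(d[8:].mean())
        assert np.mean(late) < np.mean(early)

    def test_fivefold_stimulus_ratio(self, scene, monomer_model):
        """A 5x arrival step in ground truth reads out as a 5x density ratio."""
        dens = np.concatenate([np.full(4, 5.0), np.full(4, 25.0)])
        ratios = []
        for s in range(3):
            stack, _ = sim.render_movie(scene, monomer_model, 8, seed=50 + s,
                                        density_per_frame=dens,
                                        min_separation=3 * scene.psf_sigma)
            tab = sp.detect_spots_stack(stack, scene.pixel_size, min_snr=5,
                                        psf_sigma=scene.psf_sigma)
            d = sp.spot_density(tab, scene.area_um2, per_frame=True, n_frames=8)["density"]
            ratios.append(d[4:].mean() / d[:4].mean())
        assert np.mean(ratios) == pytest.approx(5.0, rel=0.15)


class TestRollingMean:
    def test_constant_series_unchanged(self):
        tc = TimeCourse(np.arange(10.0), np.full(10, 3.3))
        np.testing.assert_allclose(sp.rolling_mean(tc, 3.0).f, 3.3)

    def test_single_sample_window_is_identity(self):
        tc = TimeCourse(np.arange(10.0), np.arange(10.0) ** 2)
        np.testing.assert_array_equal(sp.rolling_mean(tc, 1.0).f, tc.f)

    def test_step_becomes_ramp_of_window_width(self):
        t = np.arange(0.0, 30.0)
        f = (t >= 15).astype(float)
        out = sp.rolling_mean(TimeCourse(t, f), 5.0)
        interior = out.f[(t > 10) & (t < 20)]
        ramp = interior[(interior > 0) & (interior < 1)]
        assert ramp.size == 4  # 5-sample window -> 4 strictly intermediate values
        np.testing.assert_allclose(np.diff(ramp), 0.2, atol=1e-12)

    def test_subinterval_window_rejected(self):
        tc = TimeCourse(np.arange(0.0, 5.0), np.zeros(5))
        with pytest.raises(ValueError):
            sp.rolling_mean(tc, 0.4)


class TestNormalizeToBaseline:
    def test_constant_becomes_ones(self):
        tc = TimeCourse(np.arange(-3.0, 5.0), np.full(8, 7.0))
        np.testing.assert_allclose(sp.normalize_to_baseline(tc).f, 1.0)

    def test_doubling_reads_two(self):
        t = np.arange(-3.0, 5.0)
        f = np.where(t < 0, 5.0, 10.0)
        out = sp.normalize_to_baseline(TimeCourse(t, f))
        assert out.f[-1] == pytest.approx(2.0)
        assert out.f[t < 0].mean() == pytest.approx(1.0)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(-3.0, 5.0)
        with pytest.raises(ValueError):
            sp.normalize_to_baseline(TimeCourse(t, np.zeros(8)))


class TestModalBackground:
    def test_constant_image_zeroed(self):
        img = np.full((20, 20), 100.0)
        np.testing.assert_array_equal(sp.subtract_modal_background(img), 0.0)

    def test_mode_found_despite_sparse_spots(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 5.0, (100, 100))
        img[10:15, 10:15] += 2000.0
        out = sp.subtract_modal_background(img)
        # background distribution should now be centred near zero
        assert abs(np.median(out)) <= 1.0

    @given(st.integers(min_value=-200, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(99)
        base = rng.normal(100.0, 5.0, 400)
        a = sp.subtract_modal_background(base)
        b = sp.subtract_modal_background(base + shift)
        assert np.max(np.abs(a - b)) <= 1.0  # mode estimated on a 1-ADU grid

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            sp.subtract_modal_background(np.zeros(50))


class TestSpotTableIO:
    def test_round_trip_with_compatible_headers(self, tmp_path):
        tab = pd.DataFrame({
            "frame": [0, 1], "x": [1.5, 2.5], "y": [3.5, 4.5],
            "intensity": [1000.0, 1200.0], "sigma_fit": [0.09, 0.1],
        })
        path = tmp_path / "spots.csv"
        sp.write_spot_table(tab, path)
        header = path.read_text().splitlines()[0]
        assert "x [nm]" in header and "intensity [photon]" in header
        back = sp.read_spot_table(path)
        np.testing.assert_allclose(back["x"], tab["x"])
        np.testing.assert_allclose(back["intensity"], tab["intensity"])
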