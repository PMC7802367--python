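"""Ground-truth bookkeeping and statistical structure of the generator."""

import numpy as np
import pandas as pd
import pytest

from micropat import (
    CameraModel,
    FilamentScript,
    PatternSpec,
    estimate_camera_background,
    simulate_adhesion_field,
    simulate_dark_stack,
    simulate_gliding_movie,
    simulate_multiplex_series,
    simulate_pattern_image,
)

PX = 0.11


def disk(center, size_um=5.0, on_mean=500.0, on_cv=0.1, off_fraction=0.01):
    return PatternSpec("disk", center, size_um, on_mean, on_cv, off_fraction)


class TestPatternImage:
    def test_truth_selectivity_is_ratio_of_generating_means(self, camera):
        _, truth = simulate_pattern_image([disk((64, 64))], camera, (128, 128), seed=0)
        # on 500 photons, off 500*0.01=5 -> 100 before noise
        assert truth.per_pattern[1]["selectivity"] == pytest.approx(100.0)

    def test_off_fraction_one_gives_unit_selectivity(self, camera):
        spec = disk((64, 64), off_fraction=1.0)
        _, truth = simulate_pattern_image([spec], camera, (128, 128), seed=0)
        assert truth.per_pattern[1]["selectivity"] == pytest.approx(1.0)

    def test_fixed_seed_bit_identical(self, camera):
        a, _ = simulate_pattern_image([disk((64, 64))], camera, (128, 128), seed=7)
        b, _ = simulate_pattern_image([disk((64, 64))], camera, (128, 128), seed=7)
        assert np.array_equal(a.data, b.data)

    def test_truth_homogeneity_strictly_decreases_with_cv(self, camera):
        homs = []
        for cv in (0.05, 0.1, 0.2, 0.4):
            _, truth = simulate_pattern_image(
                [disk((64, 64), on_cv=cv)], camera, (128, 128), seed=0)
            homs.append(truth.per_pattern[1]["homogeneity"])
        assert all(a > b for a, b in zip(homs, homs[1:]))

    def test_realized_on_pattern_stats_match_truth(self, camera):
        spec = disk((64, 64), size_um=8.0)
        image, truth = simulate_pattern_image([spec], camera, (128, 128), seed=1)
        on = image.data[truth.pattern_labels == 1]
        expected_mean = camera.offset_mean + camera.gain * spec.on_mean
        assert on.mean() == pytest.approx(expected_mean, rel=0.01)
        expected_var = (camera.read_noise_sd ** 2 + camera.gain * spec.on_mean
                        + (camera.gain * spec.on_cv * spec.on_mean) ** 2)
        assert on.var(ddof=1) == pytest.approx(expected_var, rel=0.2)

    def test_overlapping_specs_rejected(self, camera):
        with pytest.raises(ValueError, match="overlap"):
            simulate_pattern_image([disk((64, 64)), disk((64, 66))],
                                   camera, (128, 128), seed=0)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError, match="size_um"):
            PatternSpec("disk", (10, 10), -5.0, 100.0)

    def test_pattern_touching_border_rejected(self, camera):
        with pytest.raises(ValueError, match="border|outside"):
            simulate_pattern_image([disk((0, 0))], camera, (64, 64), seed=0)


class TestDarkFrames:
    def test_mean_and_variance_converge_to_camera_model(self, camera):
        stack = simulate_dark_stack(camera, (32, 32), 150, seed=3)
        bg = estimate_camera_background(stack)
        sem = camera.read_noise_sd / np.sqrt(stack.size)
        assert abs(bg.mean - camera.offset_mean) < 3 * sem
        assert bg.variance == pytest.approx(camera.read_noise_sd ** 2, rel=0.05)


class TestMultiplex:
    @pytest.fixture
    def setup(self, camera):
        specs = [disk((32, 32), 6.0, 1000.0), disk((32, 96), 6.0, 1200.0)]
        assignment = {"a": 1, "b": 2}
        ct = pd.DataFrame([[1.0, 0.013], [0.0, 1.0]],
                          index=["a", "b"], columns=[1, 2])
        return specs, assignment, ct

    def test_truth_crosstalk_echoes_input(self, camera, setup):
        specs, assignment, ct = setup
        _, truth = simulate_multiplex_series(specs, assignment, ct, camera,
                                             (64, 128), seed=0)
        assert truth.crosstalk.equals(ct)

    def test_channel_signal_scales_with_crosstalk(self, camera, setup):
        specs, assignment, ct = setup
        images, truth = simulate_multiplex_series(specs, assignment, ct, camera,
                                                  (64, 128), seed=0)
        wrong = images["a"].data[truth.pattern_labels == 2].mean()
        expected = camera.offset_mean + camera.gain * 1000.0 * 0.013
        assert wrong == pytest.approx(expected, abs=1.0)

    def test_intended_entry_must_be_one(self, camera, setup):
        specs, assignment, ct = setup
        bad = ct.copy()
        bad.loc["a", 1] = 0.9
        with pytest.raises(ValueError, match="intended"):
            simulate_multiplex_series(specs, assignment, bad, camera, (64, 128), seed=0)

    def test_assignment_to_missing_pattern_rejected(self, camera, setup):
        specs, _, ct = setup
        with pytest.raises(ValueError, match="missing pattern"):
            simulate_multiplex_series(specs, {"a": 1, "b": 9}, ct, camera,
                                      (64, 128), seed=0)

    def test_fixed_seed_bit_identical(self, camera, setup):
        specs, assignment, ct = setup
        run1, _ = simulate_multiplex_series(specs, assignment, ct, camera,
                                            (64, 128), seed=5)
        run2, _ = simulate_multiplex_series(specs, assignment, ct, camera,
                                            (64, 128), seed=5)
        for ch in run1:
            assert np.array_equal(run1[ch].data, run2[ch].data)


class TestGlidingScripts:
    path = ((16.0, 5.0), (16.0, 495.0))
    mask = np.ones((32, 500), bool)

    def script(self, speed=0.5, duty=1.0, on_pattern=True):
        return FilamentScript(self.path, speed, duty, 1.0, on_pattern=on_pattern)

    def test_full_duty_displacement_is_exact_kinematics(self, camera):
        _, truth = simulate_gliding_movie([self.script(0.5, 1.0)], self.mask,
                                          camera, 50, seed=0, pixel_size_um=PX)
        rec = truth.filaments[0]
        # 0.5 um/s for 49 intervals of 1 s, pre-noise centerline
        assert rec["net_displacement_um"] == pytest.approx(0.5 * 49)

    def test_zero_duty_filament_never_moves(self, camera):
        _, truth = simulate_gliding_movie([self.script(0.5, 0.0)], self.mask,
                                          camera, 50, seed=0, pixel_size_um=PX)
        assert truth.filaments[0]["net_displacement_um"] == 0.0

    def test_off_pattern_filament_never_moves(self, camera):
        _, truth = simulate_gliding_movie(
            [self.script(0.5, 1.0, on_pattern=False)], self.mask, camera, 50,
            seed=0, pixel_size_um=PX)
        assert truth.filaments[0]["net_displacement_um"] == 0.0

    def test_realized_duty_within_binomial_error(self, camera):
        n = 200
        _, truth = simulate_gliding_movie([self.script(0.25, 0.7)], self.mask,
                                          camera, n, seed=0, pixel_size_um=PX)
        realized = truth.filaments[0]["duty_realized"]
        assert abs(realized - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / (n - 1))
        moving = np.array(truth.filaments[0]["moving"])
        assert realized == pytest.approx(moving.mean())

    def test_zero_frame_interval_rejected(self):
        with pytest.raises(ValueError, match="frame_interval"):
            FilamentScript(self.path, 0.5, 1.0, 0.0)

    def test_fixed_seed_bit_identical(self, camera):
        m1, _ = simulate_gliding_movie([self.script(0.5, 0.7)], self.mask,
                                       camera, 20, seed=9, pixel_size_um=PX)
        m2, _ = simulate_gliding_movie([self.script(0.5, 0.7)], self.mask,
                                       camera, 20, seed=9, pixel_size_um=PX)
        assert np.array_equal(m1.data, m2.data)


class TestAdhesionField:
    @pytest.fixture
    def labels(self):
        labels = np.zeros((220, 220), np.int32)
        rr, cc = np.mgrid[0:220, 0:220]
        for i, (r0, c0) in enumerate([(60, 60), (60, 160), (160, 60), (160, 160)], 1):
            labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= 40 ** 2] = i
        return labels

    def test_zero_off_density_puts_all_cells_on_pattern(self, labels):
        _, centroids, _ = simulate_adhesion_field(labels, 0.02, 0.0, seed=1,
                                                  pixel_size_um=PX,
                                                  cell_radius_um=0.5)
        assert len(centroids) > 0
        assert centroids["on_pattern"].all()
        on = labels > 0
        for _, row in centroids.iterrows():
            assert on[int(round(row.row)), int(round(row.col))]

    def test_counts_within_poisson_error_of_expectation(self, labels):
        _, _, truth = simulate_adhesion_field(labels, 0.05, 0.005, seed=2,
                                              pixel_size_um=PX,
                                              cell_radius_um=0.35)
        for side in ("on", "off"):
            n = truth.cells[f"n_{side}"]
            exp = truth.cells[f"expected_n_{side}"]
            assert abs(n - exp) <= 4 * np.sqrt(exp) + 1

    def test_equal_densities_expect_fifty_percent_nonspecific(self, labels):
        _, _, truth = simulate_adhesion_field(labels, 0.01, 0.01, seed=3,
                                              pixel_size_um=PX,
                                              cell_radius_um=0.5)
        assert truth.cells["expected_nonspecific_adhesion_pct"] == pytest.approx(50.0)

    def test_overpacked_density_rejected(self, labels):
        with pytest.raises(ValueError, match="packing"):
            simulate_adhesion_field(labels, 1.0, 0.0, seed=0,
                                    pixel_size_um=PX, cell_radius_um=5.0)

    def test_fixed_seed_bit_identical(self, labels):
        img1, c1, _ = simulate_adhesion_field(labels, 0.01, 0.001, seed=4,
                                              pixel_size_um=PX, cell_radius_um=0.5)
        img2, c2, _ = simulate_adhesion_field(labels, 0.01, 0.001, seed=4,
                                              pixel_size_um=PX, cell_radius_um=0.5)
        assert np.array_equal(img1.data, img2.data)
        assert c1.equals(c2)


class TestGroundTruthSidecar:
    def test_roundtrips_to_json_and_label_tiff(self, camera, tmp_path):
        import json

        import tifffile

        _, truth = simulate_pattern_image([disk((64, 64))], camera, (128, 128), seed=0)
        truth.save(tmp_path / "gt")
        with open(tmp_path / "gt.json") as fh:
            payload = json.load(fh)
        assert payload["per_pattern"]["1"]["selectivity"] == pytest.approx(100.0)
        labels = tifffile.imread(tmp_path / "gt_labels.tif")
        assert np.array_equal(labels, truth.pattern_labels)
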