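"""Cursor-trace preprocessing: coordinate conversion, Gaussian density,
face partitioning, and band-weight aggregation."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.base import clone

import facetrait as ft
from facetrait.preprocessing import DensityMap, accumulate_density


def _trajectory(points, session="s"):
    t = np.arange(len(points), dtype=float)
    samples = np.column_stack([t, np.asarray(points, dtype=float)])
    return ft.CursorTrajectory(session, "p", "v", samples)


class TestToVideoCoords:
    def test_origin_maps_to_origin(self):
        cfg = ft.ScreenConfig(stimulus_origin=(100.0, 50.0))
        out = ft.to_video_coords(_trajectory([(100, 50)]), cfg)
        assert tuple(out.samples[0, 1:]) == (0.0, 0.0)
        assert out.in_canvas[0]

    def test_zero_origin_is_identity(self):
        cfg = ft.ScreenConfig(stimulus_origin=(0.0, 0.0))
        traj = _trajectory([(10, 20), (30, 40)])
        out = ft.to_video_coords(traj, cfg)
        np.testing.assert_array_equal(out.samples, traj.samples)

    def test_out_of_canvas_sample_translated_and_flagged(self):
        cfg = ft.ScreenConfig(stimulus_origin=(100.0, 50.0))
        out = ft.to_video_coords(_trajectory([(50, 20)]), cfg)
        assert tuple(out.samples[0, 1:]) == (-50.0, -30.0)
        assert not out.in_canvas[0]

    def test_empty_trajectory_passes_through(self):
        cfg = ft.ScreenConfig()
        out = ft.to_video_coords(
            ft.CursorTrajectory("s", "p", "v", np.empty((0, 3))), cfg
        )
        assert len(out) == 0


class TestAccumulateDensity:
    def test_kernel_peaks_at_sample(self):
        dm = accumulate_density(_trajectory([(300, 400)]))
        r, c = np.unravel_index(np.argmax(dm.grid), dm.grid.shape)
        assert (c, r) == (300, 400)

    @pytest.mark.parametrize("sigma", [2.0, 10.0, 25.0])
    def test_unit_mass_per_sample(self, sigma):
        dm = accumulate_density(_trajectory([(300, 400)]), sigma_px=sigma)
        assert dm.total_mass == pytest.approx(1.0, abs=1e-3)

    def test_superposition_is_linear(self):
        one = accumulate_density(_trajectory([(200, 300)]))
        two = accumulate_density(_trajectory([(200, 300), (200, 300)]))
        np.testing.assert_allclose(two.grid, 2.0 * one.grid, rtol=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            accumulate_density(_trajectory([(10, 10)]), sigma_px=0.0)


class TestPartitionFace:
    def test_band_heights_follow_ratio(self):
        # landmarks spanning rows 100..339.5 -> bbox height 240
        frames = np.zeros((1, 68, 2))
        frames[0, :, 0] = np.linspace(200, 399.5, 68)
        frames[0, :, 1] = np.linspace(100, 339.5, 68)
        video = ft.LandmarkVideo("v", 1, "happiness", frames)
        part = ft.partition_face(video)
        assert part.bbox[1] == 100.0 and part.bbox[3] == 340.0
        assert part.band_heights == (100.0, 80.0, 60.0)

    def test_unit_ratio_cuts(self):
        part = ft.FacePartition.from_bbox((0.0, 0.0, 1.0, 2.4))
        assert part.cuts == pytest.approx((1.0, 1.8))

    def test_pairwise_ratios(self):
        part = ft.FacePartition.from_bbox((10.0, 5.0, 50.0, 77.0))
        u, m, low = part.band_heights
        assert m / u == pytest.approx(0.8)
        assert low / u == pytest.approx(0.6)

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            ft.FacePartition.from_bbox((0.0, 10.0, 5.0, 10.0))


class TestAggregateWeights:
    def _partition(self):
        return ft.FacePartition.from_bbox((200.0, 100.0, 400.0, 340.0))

    def test_all_mass_in_upper_band(self):
        grid = np.zeros((800, 600))
        grid[120:150, 250:350] = 1.0
        ow = ft.aggregate_weights(DensityMap(grid, (600, 800)), self._partition())
        assert ow.weights == (1.0, 0.0, 0.0)
        assert ow.out_of_bbox_fraction == 0.0

    def test_all_mass_outside_bbox(self):
        grid = np.zeros((800, 600))
        grid[500:600, 0:100] = 1.0
        ow = ft.aggregate_weights(DensityMap(grid, (600, 800)), self._partition())
        assert ow.weights == (0.0, 0.0, 0.0)
        assert ow.out_of_bbox_fraction == 1.0

    def test_uniform_density_recovers_band_ratios(self):
        grid = np.zeros((800, 600))
        grid[100:340, 200:400] = 1.0  # uniform over the exact bbox
        ow = ft.aggregate_weights(DensityMap(grid, (600, 800)), self._partition())
        np.testing.assert_allclose(
            ow.vector, [1 / 2.4, 0.8 / 2.4, 0.6 / 2.4], atol=1e-12
        )

    def test_zero_mass_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning):
            ow = ft.aggregate_weights(
                DensityMap(np.zeros((800, 600)), (600, 800)), self._partition()
            )
        assert ow.weights == (0.0, 0.0, 0.0)


class TestInvariants:
    def test_mass_conservation_on_random_trajectories(self):
        rng = np.random.default_rng(8)
        video = ft.gen_stimuli(1, ("disgust",), seed=4)[0]
        part = ft.partition_face(video)
        for _ in range(5):
            pts = np.column_stack(
                [rng.uniform(0, 599, 40), rng.uniform(0, 799, 40)]
            )
            dm = accumulate_density(_trajectory(pts))
            ow = ft.aggregate_weights(dm, part)
            assert sum(ow.weights) + ow.out_of_bbox_fraction == pytest.approx(1.0, abs=1e-6)

    def test_translation_equivariance(self):
        video = ft.gen_stimuli(1, ("fear",), seed=4)[0]
        pts = [(300, 350), (310, 420), (290, 500)]
        base = ft.process_session(
            _trajectory([(x + 100, y + 50) for x, y in pts]),
            video,
            config=ft.ScreenConfig(stimulus_origin=(100.0, 50.0)),
        )
        shifted = ft.process_session(
            _trajectory([(x + 400, y + 150) for x, y in pts]),
            video,
            config=ft.ScreenConfig(stimulus_origin=(400.0, 150.0)),
        )
        assert base.weights == shifted.weights

    def test_adding_in_band_samples_never_decreases_band_weight(self):
        video = ft.gen_stimuli(1, ("sadness",), seed=4)[0]
        part = ft.partition_face(video)
        x = 0.5 * (part.bbox[0] + part.bbox[2])
        y_mid = 0.5 * (part.cuts[0] + part.cuts[1])  # middle-band centre
        pts = [(x, part.bbox[1] + 5), (x, y_mid)]
        prev = ft.process_session(_trajectory(pts), video).weights[1]
        for extra in range(1, 4):
            pts = pts + [(x, y_mid)]
            cur = ft.process_session(_trajectory(pts), video).weights[1]
            assert cur >= prev - 1e-12
            prev = cur


class TestCursorWeightExtractor:
    def test_transform_produces_weight_table(self):
        video = ft.gen_stimuli(1, ("surprise",), seed=6)[0]
        ow = ft.ObservationWeights("s1", (0.5, 0.3, 0.1))
        traj = ft.gen_trajectory(ow, video, seed=1)
        table = ft.CursorWeightExtractor().fit().transform([(traj, video)])
        assert list(table.columns) == [
            "session_id", "participant_id", "stimulus_id",
            "w_upper", "w_middle", "w_low", "raw_mass_total", "out_of_bbox_fraction",
        ]
        got = table[["w_upper", "w_middle", "w_low"]].to_numpy()[0]
        assert np.abs(got - [0.5, 0.3, 0.1]).sum() <= 0.05

    def test_sklearn_params_roundtrip(self):
        ext = ft.CursorWeightExtractor(sigma_px=5.0)
        assert clone(ext).get_params()["sigma_px"] == 5.0
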