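"""Generators: trait profiles, landmark stimuli, ZIB weights, choices,
and cursor traces that round-trip through preprocessing."""

from __future__ import annotations

import numpy as np
import pytest

import facetrait as ft
from facetrait.synthetic import sample_zib_triple

from conftest import make_choice_truth, make_zib_truth


class TestGenParticipants:
    def test_fixed_seed_reproducible(self):
        a = ft.gen_participants(3, seed=1)
        b = ft.gen_participants(3, seed=1)
        assert [p.traits for p in a] == [p.traits for p in b]
        c = ft.gen_participants(3, seed=2)
        assert [p.traits for p in a] != [p.traits for p in c]

    def test_scores_truncated_to_scale(self):
        profiles = ft.gen_participants(1000, seed=2)
        scores = np.array([p.trait_vector for p in profiles])
        assert scores.min() >= 1.0 and scores.max() <= 7.0

    def test_degenerate_distribution_is_point_mass(self):
        profiles = ft.gen_participants(1000, seed=3, sd=0.0)
        scores = np.array([p.trait_vector for p in profiles])
        assert np.all(scores == 4.0)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            ft.gen_participants(0, seed=1)


class TestGenStimuli:
    def test_full_design_yields_48_videos_of_68_points(self):
        videos = ft.gen_stimuli(8, ft.EXPRESSIONS, seed=1)
        assert len(videos) == 48
        assert all(v.frames.shape[1:] == (68, 2) for v in videos)
        assert len({v.stimulus_id for v in videos}) == 48

    def test_face_occupies_expected_region(self):
        video = ft.gen_stimuli(1, ("happiness",), seed=5)[0]
        pts = video.frames.reshape(-1, 2)
        width = pts[:, 0].max() - pts[:, 0].min()
        height = pts[:, 1].max() - pts[:, 1].min()
        # face roughly 200 x 250 px on the 600 x 800 canvas
        assert 120 < width < 300 and 150 < height < 380
        assert video.duration_ms == 2500.0

    def test_fixed_seed_reproducible(self):
        a = ft.gen_stimuli(1, ("happiness",), seed=5)[0]
        b = ft.gen_stimuli(1, ("happiness",), seed=5)[0]
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_empty_expressions_rejected(self):
        with pytest.raises(ValueError):
            ft.gen_stimuli(2, (), seed=1)


class TestObservationWeightSampling:
    def test_zero_part_limit_gives_all_zero_weights(self):
        truth = make_zib_truth(alpha_zero=-40.0)  # q -> 0
        profile = ft.gen_participants(1, seed=1)[0]
        ow = ft.sample_observation_weights(profile, truth, "happiness", seed=0)
        assert ow.weights == (0.0, 0.0, 0.0)

    def test_matches_analytic_zib_law(self):
        # all coefficients 0, phi = 2: q = 1/2 and nonzero draws ~ Beta(1, 1)
        truth = make_zib_truth(phi=2.0)
        profile = ft.ParticipantProfile("p", dict.fromkeys(ft.TRAITS, 4.0))
        # traits at 4 with zero betas leave the linear predictors at 0
        rng = np.random.default_rng(42)
        draws = np.array(
            [sample_zib_triple(profile, truth.zib["happiness"], rng) for _ in range(10_000)]
        ).ravel()
        nonzero = draws[draws > 0]
        n = draws.size
        p_hat = nonzero.size / n
        se_p = np.sqrt(0.5 * 0.5 / n)
        assert abs(p_hat - 0.5) < 3 * se_p
        # Beta(1,1): mean 1/2, variance 1/12
        se_mean = np.sqrt(1.0 / 12.0 / nonzero.size)
        assert abs(nonzero.mean() - 0.5) < 3 * se_mean
        var, se_var = nonzero.var(), np.sqrt(2.0 / 45.0) / np.sqrt(nonzero.size)
        assert abs(var - 1.0 / 12.0) < 3 * se_var

    def test_rescaled_to_simplex_and_reproducible(self):
        truth = make_zib_truth(alpha_zero=40.0, alpha_beta=2.0, phi=50.0)  # big draws
        profile = ft.ParticipantProfile("p", dict.fromkeys(ft.TRAITS, 4.0))
        a = ft.sample_observation_weights(profile, truth, "fear", seed=3)
        b = ft.sample_observation_weights(profile, truth, "fear", seed=3)
        assert a.weights == b.weights
        assert sum(a.weights) <= 1.0

    def test_invalid_phi_rejected(self):
        truth = make_zib_truth()
        truth.zib["happiness"].phi = -1.0
        profile = ft.gen_participants(1, seed=1)[0]
        with pytest.raises(ValueError):
            ft.sample_observation_weights(profile, truth, "happiness", seed=0)


class TestSampleChoices:
    def test_symmetric_model_is_uniform_over_responses(self):
        truth = make_choice_truth()
        profile = ft.ParticipantProfile("p", dict.fromkeys(ft.TRAITS, 4.0))
        weights = ft.ObservationWeights("s", (0.2, 0.2, 0.2))
        rng = np.random.default_rng(0)
        counts = dict.fromkeys(ft.EXPRESSIONS, 0)
        n = 12_000
        for _ in range(n):
            trial = ft.sample_choices(profile, weights, truth, "A", rng)
            counts[trial.chosen] += 1
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for k in ft.EXPRESSIONS:
            assert abs(counts[k] / n - 1 / 6) < 4 * se

    def test_saturated_intercept_dominates(self):
        # saturate both ways: under the categorical normalization the other
        # five responses must be suppressed, not just left at logit 0
        alpha = np.full(6, -20.0)
        alpha[ft.EXPRESSIONS.index("happiness")] = 20.0
        truth = make_choice_truth(alpha=alpha)
        profile = ft.ParticipantProfile("p", dict.fromkeys(ft.TRAITS, 4.0))
        weights = ft.ObservationWeights("s", (0.3, 0.3, 0.3))
        rng = np.random.default_rng(1)
        chosen = [
            ft.sample_choices(profile, weights, truth, "A", rng).chosen
            for _ in range(500)
        ]
        assert np.mean([c == "happiness" for c in chosen]) > 0.99

    def test_fixed_seed_reproducible(self):
        truth = make_choice_truth()
        profile = ft.gen_participants(1, seed=4)[0]
        weights = ft.ObservationWeights("s", (0.5, 0.2, 0.1))
        a = [ft.sample_choices(profile, weights, truth, "A", seed=11, session_id=str(i)).chosen for i in range(20)]
        b = [ft.sample_choices(profile, weights, truth, "A", seed=11, session_id=str(i)).chosen for i in range(20)]
        assert a == b

    def test_variant_predictor_mismatch_rejected(self):
        truth = make_choice_truth()
        profile = ft.gen_participants(1, seed=4)[0]
        with pytest.raises(ValueError):
            ft.sample_choices(profile, profile.trait_vector, truth, "A", seed=0)
        truth_b = make_choice_truth(n_predictors=5)
        with pytest.raises(ValueError):
            ft.sample_choices(
                profile, ft.ObservationWeights("s", (0.3, 0.3, 0.3)), truth_b, "B", seed=0
            )


class TestGenTrajectory:
    @pytest.mark.parametrize(
        "weights",
        [(1.0, 0.0, 0.0), (0.34, 0.33, 0.33), (0.0, 0.0, 0.9), (0.2, 0.0, 0.3)],
    )
    def test_round_trip_through_preprocessing(self, weights):
        video = ft.gen_stimuli(1, ("anger",), seed=2)[0]
        ow = ft.ObservationWeights("s", weights)
        traj = ft.gen_trajectory(ow, video, seed=3)
        recovered = ft.process_session(traj, video)
        err = np.abs(recovered.vector - np.asarray(weights)).sum()
        assert err <= 0.05

    def test_weights_above_simplex_rejected(self):
        video = ft.gen_stimuli(1, ("anger",), seed=2)[0]
        with pytest.raises(ValueError):
            ow = ft.ObservationWeights("s", (0.7, 0.4, 0.2))

    def test_degenerate_policy_rejected(self):
        with pytest.raises(ValueError):
            ft.TrajectoryPolicy(duration_ms=0.0)


class TestSimulateStudy:
    def test_design_structure(self, small_study):
        # 4 participants x 12 stimuli x 2 parts
        assert len(small_study.trials) == 4 * 12 * 2
        assert len(small_study.weights) == 4 * 12  # part 2 only
        assert set(small_study.trials["part"]) == {1, 2}
        assert small_study.trials["chosen"].isin(ft.EXPRESSIONS).all()

    def test_reproducible(self):
        a = ft.simulate_study(n_participants=2, seed=3, n_actors=1, parts=(2,))
        b = ft.simulate_study(n_participants=2, seed=3, n_actors=1, parts=(2,))
        assert a.trials.equals(b.trials)
        assert a.weights.equals(b.weights)
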