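"""Generator contracts: trial timing, event statistics, forward model."""

import numpy as np
import pytest

from traceblink.synthetic import (
    SimConfig, GroundTruth, assign_populations, calcium_kernel,
    generate_event_trains, generate_experiment_schedule, generate_eye_trace,
    generate_roi_centroids, generate_trial_schedule, kernel_peak_frames,
    render_fluorescence, simulate_session, truth_binary,
)


class TestTrialSchedule:
    def test_iti_gaps_within_configured_bounds(self):
        cfg = SimConfig(n_trials=20, seed=0)
        sched = generate_trial_schedule(cfg)
        gaps_s = np.diff(sched.tone_onsets) / sched.frame_rate
        assert np.all(gaps_s >= 30.0 - 1e-9) and np.all(gaps_s <= 40.0 + 1e-9)

    def test_no_puff_means_empty_puff_list(self):
        sched = generate_trial_schedule(SimConfig(seed=1), with_puff=False)
        assert len(sched.puff_onsets) == 0

    def test_tone_puff_window_is_12_frames_at_20hz(self):
        sched = generate_trial_schedule(SimConfig(seed=2))
        assert sched.tone_puff_frames == 12
        assert np.all(sched.puff_onsets - sched.tone_onsets == 12)

    def test_session_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_trial_schedule(SimConfig(n_trials=20, seed=0),
                                    duration_s=100)

    def test_blocks_concatenate_without_overlap(self):
        cfg = SimConfig(seed=4)
        sched = generate_experiment_schedule(
            cfg, [("cond", 10, True), ("ext", 10, False)])
        assert sched.n_trials == 20
        assert list(sched.blocks[:10]) == ["cond"] * 10
        assert np.all(np.diff(sched.tone_onsets) > 0)
        # only the conditioning trials carry puffs
        assert len(sched.puff_onsets) == 10


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"resp_prob_co": 1.5}, {"cr_prob": -0.1},
        {"frame_rate": 0}, {"iti_jitter": 40.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestEventTrains:
    def test_zero_rates_give_no_events(self):
        cfg = SimConfig(n_cells=5, basal_rate=0.0, resp_prob_co=0.0,
                        resp_prob_ex=0.0, seed=0)
        sched = generate_experiment_schedule(cfg)
        truth = assign_populations(cfg)
        generate_event_trains(cfg, sched, truth)
        assert all(len(o) == 0 for o in truth.event_onsets_true)

    def test_poisson_event_count_matches_closed_form(self):
        # 1.7/min for 60 min -> mean 102 per cell; 200 cells give
        # SE = sqrt(102/200), and the empirical mean must sit within 3 SE
        cfg = SimConfig(n_cells=200, basal_rate=1.7, resp_fraction_co=0,
                        resp_fraction_ex=0, seed=9)
        sched = generate_trial_schedule(cfg, n_trials=0, duration_s=3600)
        truth = GroundTruth()
        generate_event_trains(cfg, sched, truth)
        counts = [len(o) for o in truth.event_onsets_true]
        se = np.sqrt(102 / 200)
        assert abs(np.mean(counts) - 102.0) < 3 * se

    def test_certain_responder_fires_every_conditioning_trial(self):
        cfg = SimConfig(n_cells=10, resp_prob_co=1.0, basal_rate=0.0, seed=5)
        sched = generate_experiment_schedule(cfg, [("cond", 20, True)])
        truth = assign_populations(cfg)
        generate_event_trains(cfg, sched, truth)
        for cell in truth.co_cells:
            onsets = truth.event_onsets_true[cell]
            in_window = 0
            for trial in range(20):
                a, b = sched.response_window(trial)
                in_window += np.any((onsets >= a) & (onsets < b))
            assert in_window >= 20 or len(onsets) >= 20

    def test_adding_cells_does_not_perturb_existing_ones(self):
        base = SimConfig(n_cells=5, seed=11)
        more = SimConfig(n_cells=8, seed=11)
        s1 = generate_experiment_schedule(base)
        s2 = generate_experiment_schedule(more)
        t1, t2 = GroundTruth(), GroundTruth()
        generate_event_trains(base, s1, t1)
        generate_event_trains(more, s2, t2)
        for c in range(5):
            np.testing.assert_array_equal(t1.event_onsets_true[c],
                                          t2.event_onsets_true[c])


class TestPopulations:
    def test_overlap_matches_configured_jaccard(self):
        cfg = SimConfig(n_cells=1000, seed=21)
        truth = assign_populations(cfg)
        co, ex = truth.co_cells, truth.ex_cells
        j = len(co & ex) / len(co | ex)
        assert abs(j - 0.10) < 0.02  # binomial tolerance at these set sizes
        assert len(co) == round(0.15 * 1000)
        assert len(ex) == round(0.11 * 1000)


class TestRendering:
    def test_no_events_no_noise_gives_constant_baseline(self):
        cfg = SimConfig(n_cells=1, noise_sd=0.0, seed=0)
        sched = generate_trial_schedule(cfg, n_trials=0, duration_s=60)
        truth = GroundTruth(event_onsets_true=[np.empty(0, dtype=int)])
        tr = render_fluorescence(cfg, sched, truth)[0]
        assert np.ptp(tr) == 0

    def test_single_event_peaks_at_kernel_maximum(self):
        cfg = SimConfig(n_cells=1, noise_sd=0.0, seed=0)
        sched = generate_trial_schedule(cfg, n_trials=0, duration_s=60)
        truth = GroundTruth(event_onsets_true=[np.array([400])])
        tr = render_fluorescence(cfg, sched, truth)[0]
        baseline = tr[0]
        assert np.isclose(tr.max() - baseline, 1.0)
        # closed-form peak time of the difference of exponentials
        tr_, td = cfg.kernel_rise, cfg.kernel_decay
        t_star = tr_ * td / (td - tr_) * np.log(td / tr_)
        expected_peak = 400 + int(round(t_star * cfg.frame_rate))
        assert abs(int(np.argmax(tr)) - expected_peak) <= 1

    def test_two_events_superpose_linearly(self):
        cfg = SimConfig(n_cells=1, noise_sd=0.0, seed=0)
        sched = generate_trial_schedule(cfg, n_trials=0, duration_s=60)
        both = GroundTruth(event_onsets_true=[np.array([200, 300])])
        first = GroundTruth(event_onsets_true=[np.array([200])])
        second = GroundTruth(event_onsets_true=[np.array([300])])
        t_both = render_fluorescence(cfg, sched, both)[0]
        t_a = render_fluorescence(cfg, sched, first)[0]
        t_b = render_fluorescence(cfg, sched, second)[0]
        baseline = t_a[0]
        np.testing.assert_allclose(t_both, t_a + t_b - baseline, atol=1e-12)

    def test_kernel_unit_peak_and_speed_bounds(self):
        cfg = SimConfig()
        k = calcium_kernel(cfg)
        assert np.isclose(k.max(), 1.0)
        peak = kernel_peak_frames(cfg)
        assert 1 <= peak <= 5 * cfg.frame_rate  # slower than 2 frames, < 5 s


class TestEyeTrace:
    def test_quiet_eye_dips_only_after_puffs(self):
        cfg = SimConfig(n_cells=1, cr_prob=0.0, spont_closure_rate=0.0, seed=6)
        sched = generate_experiment_schedule(cfg, [("cond", 5, True)])
        truth = assign_populations(cfg)
        generate_event_trains(cfg, sched, truth)
        eye = generate_eye_trace(cfg, sched, truth, noise_sd=0.0)
        low = np.flatnonzero(eye < 0.98)
        for f in low:  # every sub-threshold frame belongs to a puff closure
            assert any(p <= f <= p + 25 for p in sched.puff_onsets)

    def test_puff_closure_always_deeper_than_conditioned_dip(self):
        cfg = SimConfig(n_cells=1, cr_prob=1.0, seed=7)
        sched = generate_experiment_schedule(cfg, [("cond", 10, True)])
        truth = assign_populations(cfg)
        generate_event_trains(cfg, sched, truth)
        eye = generate_eye_trace(cfg, sched, truth, noise_sd=0.0)
        for trial in range(10):
            t0, t1 = sched.tone_puff_window(trial)
            puff = sched.puff_onsets[trial]
            cr_depth = 1.0 - eye[t0:t1].min()
            puff_depth = 1.0 - eye[puff:puff + 25].min()
            assert puff_depth > cr_depth


class TestReproducibility:
    def test_fixed_seed_is_bit_reproducible(self):
        a = simulate_session(SimConfig(n_cells=6, seed=77))
        b = simulate_session(SimConfig(n_cells=6, seed=77))
        np.testing.assert_array_equal(a.traces, b.traces)
        np.testing.assert_array_equal(a.eye, b.eye)
        np.testing.assert_array_equal(a.schedule.tone_onsets,
                                      b.schedule.tone_onsets)
        assert a.truth.co_cells == b.truth.co_cells

    def test_roi_centroids_respect_field_and_separation(self):
        cfg = SimConfig(n_cells=100, seed=13)
        pts, radii = generate_roi_centroids(cfg)
        assert pts.min() >= 20 and pts.max() <= cfg.fov_px - 20
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0


def test_truth_binary_marks_rising_phases_only():
    cfg = SimConfig(n_cells=1, basal_rate=0.0, seed=0)
    sched = generate_trial_schedule(cfg, n_trials=0, duration_s=60)
    truth = GroundTruth(event_onsets_true=[np.array([100])])
    b = truth_binary(cfg, sched, truth)[0]
    rise = kernel_peak_frames(cfg)
    assert b.sum() == rise + 1
    assert b[100] == 1 and b[100 + rise] == 1 and b[100 + rise + 1] == 0
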