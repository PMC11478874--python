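"""Filtering and movement-extraction rules, validated against analytic
oracles and the generator's ground-truth events."""

import numpy as np
import pytest

from kinelrp import (
    FilterSpec,
    MovementSegment,
    SegmentationError,
    SynthConfig,
    TrialExclusionError,
    detect_ice_contacts,
    detect_shot,
    extract_strides,
    generate_cohort,
    lowpass_zero_lag,
    segment_trial,
    split_turns,
)
from kinelrp.segmentation import shot_filter, sprint_filter, turn_filter

FS = 60.0


class TestLowpassZeroLag:
    def test_dc_gain_is_one(self):
        x = np.full(200, 3.7)
        out = lowpass_zero_lag(x, sprint_filter(FS))
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_passband_sine_amplitude(self):
        """Oracle: the squared 4th-order Butterworth magnitude at 0.1*fc is
        1/(1 + 0.1^8) -- attenuation far below 1%."""
        f = 0.5  # 0.1 x 5 Hz cutoff
        t = np.arange(int(20 / f * FS)) / FS  # 20 cycles
        x = np.sin(2 * np.pi * f * t)
        out = lowpass_zero_lag(x, sprint_filter(FS))
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        expected_gain = 1.0 / (1.0 + 0.1**8)
        amp = np.max(np.abs(out[mid]))
        assert abs(amp - expected_gain) < 0.01

    def test_zero_phase_on_symmetric_pulse(self):
        k = 150
        t = np.arange(300)
        x = np.exp(-0.5 * ((t - k) / 6.0) ** 2)
        out = lowpass_zero_lag(x, sprint_filter(FS))
        assert int(np.argmax(out)) == k

    def test_zero_lag_cross_correlation(self):
        k = 100
        x = np.exp(-0.5 * ((np.arange(200) - k) / 5.0) ** 2)
        out = lowpass_zero_lag(x, shot_filter(FS))
        xc = np.correlate(out - out.mean(), x - x.mean(), mode="full")
        assert int(np.argmax(xc)) - (len(x) - 1) == 0

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass_zero_lag(np.zeros(10), sprint_filter(FS))

    def test_non_finite_errors(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            lowpass_zero_lag(x, sprint_filter(FS))

    def test_filterspec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(cutoff=40.0, sample_rate=60.0)
        with pytest.raises(ValueError):
            FilterSpec(cutoff=5.0, sample_rate=60.0, order=3)


class TestIceContacts:
    def test_noiseless_recovery(self, sprint_noiseless):
        cfg, trials = sprint_noiseless
        for trial in trials:
            for side in "LR":
                det = detect_ice_contacts(
                    trial.raw_signals[f"foot_vert_velocity_{side}"], sprint_filter(FS)
                )
                truth = trial.truth_events[f"ice_contact_{side}"]
                assert len(det) == len(truth)
                assert max(abs(d - t) for d, t in zip(det, truth)) <= 1

    def test_flat_signal_gives_empty_list(self):
        assert detect_ice_contacts(np.zeros(400), sprint_filter(FS)) == []

    def test_noisy_recovery_within_two_samples(self):
        """All truth contacts recovered within +/- 2 samples under noise at
        ~10% of the signal amplitude."""
        cfg = SynthConfig(
            n_participants=2, drill="sprint", noise_sd=1.0, raw_noise_scale=0.15, seed=9
        )
        for trial in generate_cohort(cfg):
            for side in "LR":
                det = detect_ice_contacts(
                    trial.raw_signals[f"foot_vert_velocity_{side}"], sprint_filter(FS)
                )
                truth = trial.truth_events[f"ice_contact_{side}"]
                for tc in truth:
                    assert min(abs(d - tc) for d in det) <= 2


class TestExtractStrides:
    LEFT = [10, 70, 130, 190]
    RIGHT = [40, 100, 160, 220]

    def test_three_per_foot(self):
        segs = extract_strides(self.LEFT, self.RIGHT, n_per_foot=3)
        spans = [(s.start_idx, s.end_idx) for s in segs]
        assert spans == [(10, 70), (70, 130), (130, 190), (40, 100), (100, 160), (160, 220)]
        assert [s.side_or_direction for s in segs] == ["left"] * 3 + ["right"] * 3

    def test_one_per_foot(self):
        segs = extract_strides(self.LEFT, self.RIGHT, n_per_foot=1)
        assert [(s.start_idx, s.end_idx) for s in segs] == [(10, 70), (40, 100)]

    def test_insufficient_contacts_raise_exclusion(self):
        with pytest.raises(TrialExclusionError):
            extract_strides([10, 70, 130], self.RIGHT, n_per_foot=3)


class TestDetectShot:
    def test_synthetic_shot_recovered(self, shot_noiseless):
        _, trials = shot_noiseless
        for trial in trials:
            seg = detect_shot(
                trial.raw_signals["shoulder_angvel_L"],
                trial.raw_signals["shoulder_angvel_R"],
                trial.raw_signals["hand_vert_velocity_L"],
                trial.raw_signals["hand_vert_velocity_R"],
                shot_filter(FS),
            )
            assert seg.side_or_direction == "right"
            assert abs(seg.start_idx - trial.truth_events["shot_start"][0]) <= 2
            assert abs(seg.end_idx - trial.truth_events["shot_end"][0]) <= 2

    def test_mirrored_shot_flips_side(self, shot_noiseless):
        _, trials = shot_noiseless
        trial = trials[0]
        seg = detect_shot(
            trial.raw_signals["shoulder_angvel_R"],
            trial.raw_signals["shoulder_angvel_L"],
            trial.raw_signals["hand_vert_velocity_R"],
            trial.raw_signals["hand_vert_velocity_L"],
            shot_filter(FS),
        )
        assert seg.side_or_direction == "left"
        assert abs(seg.start_idx - trial.truth_events["shot_start"][0]) <= 2

    def test_zero_hand_velocity_fails(self, shot_noiseless):
        _, trials = shot_noiseless
        trial = trials[0]
        zeros = np.zeros(trial.n_samples)
        with pytest.raises(SegmentationError):
            detect_shot(
                trial.raw_signals["shoulder_angvel_L"],
                trial.raw_signals["shoulder_angvel_R"],
                zeros,
                zeros,
                shot_filter(FS),
            )

    def test_ambiguous_side_warns(self, shot_noiseless):
        _, trials = shot_noiseless
        trial = trials[0]
        sh = trial.raw_signals["shoulder_angvel_R"]
        with pytest.warns(UserWarning, match="ambiguous"):
            detect_shot(
                sh * 0.99,
                sh,
                trial.raw_signals["hand_vert_velocity_L"],
                trial.raw_signals["hand_vert_velocity_R"],
                shot_filter(FS),
            )


class TestSplitTurns:
    def test_analytic_sine(self):
        """sin(2*pi*t/T) over 3.5 periods changes sign every T/2; interior
        segments alternate direction."""
        T = 8.0
        t = np.arange(int(3.5 * T * FS)) / FS
        x = np.sin(2 * np.pi * t / T)
        segs = split_turns(x, turn_filter(FS), n_turns=5)
        half = T / 2 * FS
        for s in segs:
            assert abs(s.length - half) <= 2
        dirs = [s.side_or_direction for s in segs]
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_noiseless_truth_boundaries(self, turn_noiseless):
        cfg, trials = turn_noiseless
        for trial in trials:
            segs = split_turns(
                trial.raw_signals["pelvis_angvel_z"], turn_filter(FS), n_turns=6
            )
            truth = trial.truth_events["turn_boundary"]
            assert len(segs) == 6
            for seg, b0, b1 in zip(segs, truth[:-1], truth[1:]):
                assert abs(seg.start_idx - b0) <= 2
                assert abs(seg.end_idx - b1) <= 2

    def test_all_positive_signal_is_excluded(self):
        with pytest.raises(TrialExclusionError):
            split_turns(np.ones(600) + 0.1, turn_filter(FS), n_turns=2)


class TestSegmentTrial:
    def test_sprint_six_strides_crossover_two(self, sprint_noiseless):
        _, trials = sprint_noiseless
        assert len(segment_trial(trials[0])) == 6
        cfg = SynthConfig(n_participants=2, drill="crossover", noise_sd=0.0, seed=7)
        trial = generate_cohort(cfg)[0]
        assert len(segment_trial(trial)) == 2

    def test_determinism(self, sprint_noiseless):
        _, trials = sprint_noiseless
        assert segment_trial(trials[0]) == segment_trial(trials[0])

    def test_same_foot_segments_contiguous(self, sprint_noiseless):
        _, trials = sprint_noiseless
        segs = segment_trial(trials[0])
        for side in ("left", "right"):
            own = [s for s in segs if s.side_or_direction == side]
            for a, b in zip(own, own[1:]):
                assert a.end_idx == b.start_idx

    def test_segment_validation(self):
        with pytest.raises(ValueError, match="empty segment"):
            MovementSegment(
                segment_type="stride", side_or_direction="left", start_idx=5, end_idx=5
            )
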