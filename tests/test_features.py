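"""Time normalization, ratio-preserving scaling and feature-vector layout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinelrp import (
    ChannelMap,
    DEFAULT_CATALOG,
    SynthConfig,
    build_feature_vector,
    generate_cohort,
    normalize_participant,
    resample_to_cycle,
    segment_trial,
)
from kinelrp.features import (
    SegmentTrajectories,
    extract_segment_trajectories,
    featurize_cohort,
    flag_unreliable_dofs,
)
from kinelrp.segmentation import MovementSegment


class TestResample:
    def test_length_100_uniform_grid_is_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        np.testing.assert_allclose(resample_to_cycle(y, 100), y, atol=1e-12)

    def test_sine_against_analytic_oracle(self):
        t = np.linspace(0.0, 1.0, 37)
        y = np.sin(2 * np.pi * t)
        out = resample_to_cycle(y, 100)
        target = np.sin(2 * np.pi * np.linspace(0.0, 1.0, 100))
        assert np.max(np.abs(out - target)) < 1e-3

    def test_linear_ramp_reproduced_exactly(self):
        for n in (5, 23, 250):
            y = np.linspace(0.0, 1.0, n)
            np.testing.assert_allclose(
                resample_to_cycle(y, 100), np.linspace(0.0, 1.0, 100), atol=1e-12
            )

    def test_endpoints_preserved(self):
        y = np.array([3.0, -1.0, 4.0, 1.0, -5.0])
        out = resample_to_cycle(y, 100)
        assert out[0] == pytest.approx(3.0, abs=1e-12)
        assert out[-1] == pytest.approx(-5.0, abs=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        once = resample_to_cycle(rng.normal(size=63), 100)
        twice = resample_to_cycle(once, 100)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match=">= 4 samples"):
            resample_to_cycle(np.array([1.0, 2.0, 3.0]), 100)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        coeffs=st.tuples(
            st.floats(-5, 5), st.floats(-5, 5)
        ),
        n=st.integers(min_value=4, max_value=60),
    )
    def test_property_affine_functions_reproduced(self, coeffs, n):
        a, b = coeffs
        y = a * np.linspace(0, 1, n) + b
        np.testing.assert_allclose(
            resample_to_cycle(y, 100), a * np.linspace(0, 1, 100) + b, atol=1e-9
        )


def _seg_traj(pid, cond, data):
    seg = MovementSegment(
        segment_type="stride",
        side_or_direction="left",
        start_idx=0,
        end_idx=10,
        participant_id=pid,
        condition=cond,
    )
    return SegmentTrajectories(segment=seg, trajectories=data)


class TestNormalizeParticipant:
    def test_definition_arithmetic(self):
        cm = ChannelMap(blocks=("hip_flexext",), n_points=3)
        seg = _seg_traj("S01", "Equipment", {"hip_flexext": np.array([-30.0, 15.0, 30.0])})
        out, scales = normalize_participant([seg], {"hip_flexext": 0.5}, cm)
        np.testing.assert_allclose(
            out[0].trajectories["hip_flexext"], [-0.5, 0.25, 0.5]
        )
        assert scales["hip_flexext"] == 30.0

    def test_reference_dof_spans_unit_interval(self):
        cm = ChannelMap(blocks=("shoulder_abdadd",), n_points=2)
        seg = _seg_traj("S01", "Equipment", {"shoulder_abdadd": np.array([-90.0, 90.0])})
        out, _ = normalize_participant([seg], {"shoulder_abdadd": 1.0}, cm)
        np.testing.assert_allclose(out[0].trajectories["shoulder_abdadd"], [-1.0, 1.0])

    def test_ratio_preservation_between_dofs(self):
        """Oracle: direct computation of both scalings.  Equal raw amplitudes
        with ratios 1.0 and 0.25 end up 4:1 after normalization."""
        cm = ChannelMap(blocks=("a", "b"), n_points=3)
        raw = np.array([-20.0, 0.0, 20.0])
        seg = _seg_traj("S01", "Equipment", {"a": raw.copy(), "b": raw.copy()})
        out, _ = normalize_participant([seg], {"a": 1.0, "b": 0.25}, cm)
        amp_a = np.max(np.abs(out[0].trajectories["a"]))
        amp_b = np.max(np.abs(out[0].trajectories["b"]))
        assert amp_a / amp_b == pytest.approx(4.0)

    def test_pooled_over_conditions(self):
        cm = ChannelMap(blocks=("a",), n_points=2)
        s1 = _seg_traj("S01", "Equipment", {"a": np.array([5.0, 10.0])})
        s2 = _seg_traj("S01", "NoEquipment", {"a": np.array([-40.0, 20.0])})
        out, scales = normalize_participant([s1, s2], {"a": 1.0}, cm)
        assert scales["a"] == 40.0  # pooled max over both conditions
        np.testing.assert_allclose(out[0].trajectories["a"], [0.125, 0.25])

    def test_constant_zero_dof_warns_and_zeros(self):
        cm = ChannelMap(blocks=("a",), n_points=2)
        seg = _seg_traj("S01", "Equipment", {"a": np.zeros(2)})
        with pytest.warns(UserWarning, match="identically zero"):
            out, _ = normalize_participant([seg], {"a": 1.0}, cm)
        np.testing.assert_array_equal(out[0].trajectories["a"], [0.0, 0.0])

    def test_mixed_participants_rejected(self):
        cm = ChannelMap(blocks=("a",), n_points=2)
        s1 = _seg_traj("S01", "Equipment", {"a": np.ones(2)})
        s2 = _seg_traj("S02", "Equipment", {"a": np.ones(2)})
        with pytest.raises(ValueError, match="one participant"):
            normalize_participant([s1, s2], {"a": 1.0}, cm)


class TestChannelMap:
    def test_unilateral_and_bilateral_lengths(self):
        assert len(ChannelMap.unilateral(DEFAULT_CATALOG)) == 1200
        assert len(ChannelMap.bilateral(DEFAULT_CATALOG)) == 2400

    def test_bijection_round_trip(self):
        cm = ChannelMap.bilateral(DEFAULT_CATALOG)
        for pos in range(len(cm)):
            block, t = cm.channel_at(pos)
            assert cm.position(block, t) == pos

    def test_out_of_range(self):
        cm = ChannelMap.unilateral(DEFAULT_CATALOG)
        with pytest.raises(IndexError):
            cm.channel_at(1200)
        with pytest.raises(IndexError):
            cm.position("hip_flexext", 100)


@pytest.fixture(scope="module")
def sprint_dataset():
    cfg = SynthConfig(n_participants=3, drill="sprint", seed=21)
    trials = generate_cohort(cfg)
    segs = {i: segment_trial(t) for i, t in enumerate(trials)}
    return featurize_cohort(trials, segs, bilateral=False)


class TestFeatureVectors:
    def test_sprint_vector_length_1200(self, sprint_dataset):
        assert sprint_dataset.X.shape[1] == 1200

    def test_crossover_vector_length_2400(self):
        cfg = SynthConfig(n_participants=2, drill="crossover", seed=21)
        trials = generate_cohort(cfg)
        segs = {i: segment_trial(t) for i, t in enumerate(trials)}
        ds = featurize_cohort(trials, segs, bilateral=True)
        assert ds.X.shape[1] == 2400

    def test_all_values_within_unit_interval(self, sprint_dataset):
        assert np.all(sprint_dataset.X >= -1.0) and np.all(sprint_dataset.X <= 1.0)

    def test_per_dof_bound_is_rom_ratio(self, sprint_dataset):
        cm = sprint_dataset.channel_map
        ratios = DEFAULT_CATALOG.ratios()
        for block in cm.blocks:
            vals = sprint_dataset.X[:, cm.block_slice(block)]
            assert np.max(np.abs(vals)) <= ratios[block] + 1e-12

    def test_block_slice_round_trip(self):
        """Slicing the vector at a channel-map position returns exactly the
        stored trajectory value (bijection contract on real data)."""
        cfg = SynthConfig(n_participants=2, drill="sprint", seed=3)
        trials = generate_cohort(cfg)
        trial = trials[0]
        seg = segment_trial(trial)[0]
        st_raw = extract_segment_trajectories(trial, seg, bilateral=False)
        cm = ChannelMap.unilateral(DEFAULT_CATALOG)
        fv = build_feature_vector(st_raw, cm)
        pos = cm.position("knee_flexext", 0)
        assert fv.values[pos] == st_raw.trajectories["knee_flexext"][0]

    def test_missing_channel_errors(self):
        cm = ChannelMap(blocks=("a", "b"), n_points=2)
        seg = _seg_traj("S01", "Equipment", {"a": np.zeros(2)})
        with pytest.raises(KeyError, match="missing channels"):
            build_feature_vector(seg, cm)

    def test_feature_frame_roundtrip(self, sprint_dataset):
        df = sprint_dataset.to_frame()
        from kinelrp.features import FeatureDataset

        back = FeatureDataset.from_frame(df, 100)
        np.testing.assert_allclose(back.X, sprint_dataset.X)
        assert back.channel_map.blocks == sprint_dataset.channel_map.blocks


def test_reliability_screen_flags_null_dofs(reduced_catalog):
    """DOFs with no injected condition effect fall below the 1-degree
    reliability threshold in a noise-free cohort; the effect DOF does not."""
    from kinelrp import EffectSpec

    cfg = SynthConfig(
        n_participants=3,
        drill="sprint",
        effects=(EffectSpec(dof="knee_flexext", window=(30, 70), offset_deg=8.0),),
        participant_sd=0.0,
        noise_sd=0.0,
        seed=13,
        catalog=reduced_catalog,
    )
    trials = generate_cohort(cfg)
    segs = {i: segment_trial(t) for i, t in enumerate(trials)}
    raw_by_pid = {}
    for ti, seg_list in segs.items():
        for seg in seg_list:
            stj = extract_segment_trajectories(
                trials[ti], seg, catalog=reduced_catalog, bilateral=False
            )
            raw_by_pid.setdefault(trials[ti].participant_id, []).append(stj)
    ds = featurize_cohort(trials, segs, catalog=reduced_catalog, bilateral=False)
    flagged = flag_unreliable_dofs(ds, raw_by_pid)
    assert "knee_flexext" not in flagged
    assert "hip_flexext" in flagged
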