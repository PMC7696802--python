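import numpy as np
import pytest

from infantmotion import preprocessing, synthetic
from infantmotion.clustering import ActivityLabel
from infantmotion.sensorlog import check_sequence_continuity, segment_stream
from infantmotion.synthetic import (
    LabeledStream,
    apply_nuisance,
    default_regime_specs,
    generate_stream,
    segment_labels,
)


def single_regime(label, duration=240, seed=0, **kw):
    spec = {label: default_regime_specs()[label]}
    return generate_stream(spec, total_duration_s=duration, seed=seed, **kw)


class TestGeneration:
    def test_sample_count_arithmetic(self):
        ls = generate_stream(total_duration_s=600, seed=0)
        assert len(ls) == 24000
        assert len(ls.labels) == 24000

    def test_deterministic_given_seed(self):
        a = generate_stream(total_duration_s=30, seed=9)
        b = generate_stream(total_duration_s=30, seed=9)
        assert a.stream.records == b.stream.records
        assert (a.labels == b.labels).all()
        assert a.nuisance == b.nuisance

    def test_sequence_numbers_continuous_mod_256(self):
        ls = generate_stream(total_duration_s=30, seed=1)
        assert check_sequence_continuity(ls.stream) == []

    def test_values_within_sensor_range(self):
        for seed in range(3):
            ls = generate_stream(total_duration_s=120, seed=seed)
            accel = ls.stream.accel_array()
            assert accel.min() >= -1000 and accel.max() <= 1000

    def test_labels_piecewise_constant_all_four_present(self):
        ls = generate_stream(total_duration_s=600, seed=2)
        assert set(np.unique(ls.labels)) == {0, 1, 2, 3}

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_stream(total_duration_s=2)
        with pytest.raises(ValueError):
            generate_stream(rate_hz=0)


class TestCalibration:
    def test_sleeping_cumulative_band(self):
        vals = [preprocessing.final_cumulative(
            segment_stream(single_regime(ActivityLabel.SLEEPING, seed=s).stream)).mean()
            for s in range(2)]
        assert all(200 <= v <= 1500 for v in vals)

    def test_strong_movement_cumulative_band(self):
        vals = [preprocessing.final_cumulative(
            segment_stream(single_regime(ActivityLabel.STRONG_MOVEMENT, seed=s).stream)).mean()
            for s in range(2)]
        assert all(3000 <= v <= 9000 for v in vals)

    def test_intensity_strictly_ordered_across_seeds(self):
        for seed in range(3):
            means = {}
            for label in (ActivityLabel.SLEEPING, ActivityLabel.WEAK_MOVEMENT,
                          ActivityLabel.STRONG_MOVEMENT):
                ls = single_regime(label, duration=160, seed=seed)
                means[label] = preprocessing.final_cumulative(
                    segment_stream(ls.stream)).mean()
            assert (means[ActivityLabel.SLEEPING]
                    < means[ActivityLabel.WEAK_MOVEMENT]
                    < means[ActivityLabel.STRONG_MOVEMENT])

    def test_external_force_has_largest_transient_step(self):
        steps = {}
        for label in (ActivityLabel.STRONG_MOVEMENT, ActivityLabel.EXTERNAL_FORCE):
            ls = single_regime(label, duration=160, seed=1)
            steps[label] = preprocessing.max_step(segment_stream(ls.stream)).mean()
        assert steps[ActivityLabel.EXTERNAL_FORCE] > 1.5 * steps[ActivityLabel.STRONG_MOVEMENT]


class TestSegmentLabels:
    def test_homogeneous_window(self):
        ls = LabeledStream(stream=None, labels=np.full(200, 2))
        assert (segment_labels(ls) == 2).all()

    def test_majority_rule(self):
        labels = np.array([0] * 96 + [1] * 64)  # 60% / 40%
        ls = LabeledStream(stream=None, labels=labels)
        assert segment_labels(ls)[0] == 0

    def test_tie_takes_midpoint_label(self):
        labels = np.array([3] * 80 + [1] * 80)  # 50/50; midpoint sample is 1
        ls = LabeledStream(stream=None, labels=labels)
        assert segment_labels(ls)[0] == 1

    def test_too_short_stream_yields_nothing(self):
        ls = LabeledStream(stream=None, labels=np.zeros(100, dtype=int))
        assert segment_labels(ls).size == 0


class TestNuisance:
    def test_identity_nuisance_is_noop(self):
        ls = generate_stream(total_duration_s=20, seed=5, nuisance=False)
        out = apply_nuisance(ls.stream)
        assert out.records == ls.stream.records

    def test_offset_leaves_preprocessing_unchanged(self):
        ls = generate_stream(total_duration_s=30, seed=5, nuisance=False)
        shifted = apply_nuisance(ls.stream, offset=(50, -120, 30))
        a = preprocessing.preprocess_segments(segment_stream(ls.stream))
        b = preprocessing.preprocess_segments(segment_stream(shifted))
        assert np.allclose(a, b)

    def test_sign_flip_leaves_preprocessing_unchanged(self):
        ls = generate_stream(total_duration_s=30, seed=5, nuisance=False)
        flipped = apply_nuisance(ls.stream, sign_flips=(-1, 1, -1))
        a = preprocessing.preprocess_segments(segment_stream(ls.stream))
        b = preprocessing.preprocess_segments(segment_stream(flipped))
        assert np.allclose(a, b)

    def test_nuisance_recorded_per_recording(self):
        ls = generate_stream(total_duration_s=20, seed=6)
        assert set(ls.nuisance) == {"sign_flips", "permutation", "offset"}
        assert sorted(ls.nuisance["permutation"]) == [0, 1, 2]
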