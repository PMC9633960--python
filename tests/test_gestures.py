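"""Gesture feature encoding, the online correlation/STDP classifier, the
synthetic generators, and the abstract trajectory code."""

import numpy as np
import pandas as pd
import pytest

from spikeintent.gestures import (
    ClassifierState,
    FEATURE_NAMES,
    GESTURE_LABELS,
    GESTURE_PROTOTYPES,
    N_FEATURES,
    TRAJECTORY_ACTIONS,
    TRAJECTORY_STATES,
    classify_frozen,
    classify_online,
    encode_joint_stream,
    encode_trajectory_state,
    generate_synthetic_gestures,
    generate_trajectory_sequence,
    learn_batch,
    patterns_from_csv,
    patterns_to_csv,
    synthetic_joint_stream,
    train_and_evaluate,
)


def feature(name):
    return FEATURE_NAMES.index(name)


def static_stream(hand_z=0.12):
    base = {
        "left_shoulder": np.array([-0.2, 1.4, 0.0]),
        "right_shoulder": np.array([0.2, 1.4, 0.0]),
        "left_hand": np.array([-0.2, 0.9, hand_z]),
        "right_hand": np.array([0.2, 0.9, hand_z]),
    }
    return {k: np.tile(v, (5, 1)) for k, v in base.items()}


class TestEncodeJointStream:
    def test_static_stream_is_silent(self):
        pattern = encode_joint_stream(static_stream())
        assert not pattern.any()

    def test_both_hands_toward_body(self):
        stream = static_stream()
        for hand in ("left_hand", "right_hand"):
            stream[hand][-1, 2] -= 0.12  # pull both hands onto the body plane
        pattern = encode_joint_stream(stream)
        active = {FEATURE_NAMES[i] for i in np.where(pattern == 1)[0]}
        assert active == {"left_toward_body", "right_toward_body"}

    def test_single_axis_movement(self):
        stream = static_stream()
        stream["right_hand"][-1, 1] += 0.12  # 2x the displacement cutoff
        pattern = encode_joint_stream(stream)
        movement = pattern[:12]
        assert movement[feature("right_up")] == 1
        assert movement.sum() == 1

    def test_above_requires_lateral_proximity(self):
        # a hand high over the LEFT shoulder is not "above the right shoulder"
        stream = static_stream()
        stream["left_hand"][-1] = [-0.2, 1.48, 0.12]
        pattern = encode_joint_stream(stream)
        assert pattern[feature("left_above_left_shoulder")] == 1
        assert pattern[feature("left_above_right_shoulder")] == 0

    def test_overlap_feature(self):
        stream = static_stream()
        stream["left_hand"][-1] = [-0.2, 1.4, 0.0]
        pattern = encode_joint_stream(stream)
        assert pattern[feature("left_overlaps_left_shoulder")] == 1
        assert pattern[feature("left_overlaps_right_shoulder")] == 0

    def test_dataframe_input(self):
        rows = []
        for joint, coords in static_stream().items():
            for t, (x, y, z) in enumerate(coords):
                rows.append({"frame": t, "joint": joint, "x": x, "y": y, "z": z})
        pattern = encode_joint_stream(pd.DataFrame(rows))
        assert not pattern.any()

    def test_missing_joint_rejected(self):
        stream = static_stream()
        del stream["left_shoulder"]
        with pytest.raises(ValueError):
            encode_joint_stream(stream)

    def test_nonfinite_rejected(self):
        stream = static_stream()
        stream["left_hand"][0, 0] = np.nan
        with pytest.raises(ValueError):
            encode_joint_stream(stream)


class TestPrototypesAndStreams:
    def test_twelve_distinct_prototypes(self):
        patterns = [tuple(p) for p in GESTURE_PROTOTYPES.values()]
        assert len(patterns) == 12
        assert len(set(patterns)) == 12

    def test_overhead_gesture_has_both_above_features(self):
        j = GESTURE_PROTOTYPES["J"]
        assert j[feature("left_above_right_shoulder")] == 1
        assert j[feature("right_above_left_shoulder")] == 1

    @pytest.mark.parametrize("gesture", GESTURE_LABELS)
    def test_synthetic_stream_realises_prototype(self, gesture):
        """Encoding a generated joint stream reproduces the gesture's code."""
        stream = synthetic_joint_stream(gesture, seed=5)
        np.testing.assert_array_equal(
            encode_joint_stream(stream), GESTURE_PROTOTYPES[gesture]
        )

    def test_encoding_deterministic(self):
        s1 = synthetic_joint_stream("A", seed=9)
        s2 = synthetic_joint_stream("A", seed=9)
        np.testing.assert_array_equal(
            encode_joint_stream(s1), encode_joint_stream(s2)
        )

    def test_unknown_gesture(self):
        with pytest.raises(ValueError):
            synthetic_joint_stream("Z")


class TestGenerator:
    def test_noise_free_samples_equal_prototypes(self):
        patterns, labels = generate_synthetic_gestures(12, 3, noise=0.0, seed=0)
        for p, l in zip(patterns, labels):
            np.testing.assert_array_equal(p, GESTURE_PROTOTYPES[l])

    def test_deterministic_given_seed(self):
        a = generate_synthetic_gestures(12, 30, noise=0.05, seed=42)
        b = generate_synthetic_gestures(12, 30, noise=0.05, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[0].shape == (360, N_FEATURES)

    def test_batch_ordering(self):
        _, labels = generate_synthetic_gestures(4, 2, noise=0.0, seed=0)
        assert list(labels) == ["A", "B", "C", "D", "A", "B", "C", "D"]

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            generate_synthetic_gestures(13, 1)
        with pytest.raises(ValueError):
            generate_synthetic_gestures(12, 1, noise=0.5)

    def test_csv_round_trip(self, tmp_path):
        patterns, labels = generate_synthetic_gestures(12, 2, noise=0.1, seed=1)
        path = tmp_path / "gestures.csv"
        patterns_to_csv(patterns, labels, path)
        p2, l2 = patterns_from_csv(path)
        np.testing.assert_array_equal(p2, patterns)
        assert list(l2) == list(labels)


class TestClassifier:
    def test_first_pattern_recruits_class_zero(self):
        state = ClassifierState()
        cls, is_new, state = classify_online(state, GESTURE_PROTOTYPES["A"])
        assert (cls, is_new) == (0, True)

    def test_identical_pattern_matches_with_unit_correlation(self):
        state = ClassifierState()
        classify_online(state, GESTURE_PROTOTYPES["A"])
        cls, is_new, state = classify_online(state, GESTURE_PROTOTYPES["A"])
        assert (cls, is_new) == (0, False)

    def test_orthogonal_pattern_recruits(self):
        state = ClassifierState()
        classify_online(state, GESTURE_PROTOTYPES["A"])
        cls, is_new, _ = classify_online(state, GESTURE_PROTOTYPES["L"])
        assert is_new and cls == 1

    def test_thirteenth_orthogonal_prototype_recruits(self):
        state = ClassifierState()
        for label in GESTURE_LABELS:
            classify_online(state, GESTURE_PROTOTYPES[label])
        novel = np.zeros(N_FEATURES, dtype=np.uint8)
        novel[feature("left_away_from_body")] = 1  # unused by all 12 prototypes
        cls, is_new, _ = classify_online(state, novel)
        assert is_new and cls == state.n_classes - 1

    def test_silent_pattern_rejected(self):
        with pytest.raises(ValueError):
            classify_online(ClassifierState(), np.zeros(N_FEATURES, dtype=np.uint8))

    def test_theta_bounds(self):
        with pytest.raises(ValueError):
            ClassifierState(theta=1.5)

    def test_learn_batch_enrolls_and_stabilises(self):
        state = ClassifierState()
        protos = [GESTURE_PROTOTYPES[l] for l in GESTURE_LABELS]
        first = learn_batch(state, protos)
        assert first == list(range(12))
        second = learn_batch(state, protos)
        assert second == first  # clean repeats map to the same target neurons

    def test_frozen_classification(self):
        state = ClassifierState()
        learn_batch(state, [GESTURE_PROTOTYPES[l] for l in GESTURE_LABELS])
        for i, label in enumerate(GESTURE_LABELS):
            assert classify_frozen(state, GESTURE_PROTOTYPES[label]) == i

    def test_frozen_requires_learned_classes(self):
        with pytest.raises(ValueError):
            classify_frozen(ClassifierState(), GESTURE_PROTOTYPES["A"])

    def test_batch_refractory_online_mode(self):
        """A target neuron that already won this batch cannot win again; a
        superset gesture therefore recruits instead of being absorbed."""
        state = ClassifierState(batch_refractory=True)
        state.begin_batch()
        cls_f, _, state = classify_online(state, GESTURE_PROTOTYPES["F"])
        cls_g, is_new, state = classify_online(state, GESTURE_PROTOTYPES["G"])
        assert is_new and cls_g != cls_f
        state.begin_batch()
        cls_f2, new_f, state = classify_online(state, GESTURE_PROTOTYPES["F"])
        cls_g2, new_g, state = classify_online(state, GESTURE_PROTOTYPES["G"])
        assert (cls_f2, new_f) == (cls_f, False)
        assert (cls_g2, new_g) == (cls_g, False)


class TestOnlineLearningCurve:
    def test_noise_free_protocol_is_perfect(self):
        accs = train_and_evaluate(2, noise=0.0, seed=0)
        assert accs == [1.0, 1.0]

    def test_accuracy_improves_with_batches(self):
        """Training helps: final-batch accuracy beats the first batch unless
        the classifier was already converged (>= 0.9) at enrollment."""
        for seed in range(1, 6):
            accs = train_and_evaluate(6, noise=0.05, seed=seed)
            assert accs[-1] >= accs[0] or accs[0] >= 0.9

    def test_low_noise_separability_seed_one(self):
        accs = train_and_evaluate(6, noise=0.05, seed=1)
        assert accs[-1] >= 0.90


class TestTrajectory:
    def test_one_hot_codes(self):
        for i, label in enumerate(TRAJECTORY_STATES):
            code = encode_trajectory_state(label)
            assert code.sum() == 1 and code[i] == 1

    def test_centered_and_missing_line(self):
        assert encode_trajectory_state("line_centered")[0] == 1   # move forward
        assert encode_trajectory_state("no_line")[1] == 1         # move backward

    def test_state_action_pairing(self):
        assert len(TRAJECTORY_STATES) == len(TRAJECTORY_ACTIONS) == 6
        assert TRAJECTORY_ACTIONS[TRAJECTORY_STATES.index("line_turns_left")] == "turn_left"

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            encode_trajectory_state("spiral")

    def test_sequence_generator_deterministic(self):
        assert generate_trajectory_sequence(20, seed=4) == generate_trajectory_sequence(20, seed=4)
        assert set(generate_trajectory_sequence(200, seed=0)) == set(TRAJECTORY_STATES)
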