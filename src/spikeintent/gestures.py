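"""Perceptual front-end: 20-feature hand-gesture encoding, an online
correlation-gated STDP classifier, and the abstract 6-state trajectory code.

A depth camera provides 3-D joint coordinates; 20 binary feature neurons
summarise a gesture — for each hand, six movement directions (up, down,
left, right, toward the body, away from the body) and four positions
relative to the shoulders (overlaps left/right shoulder, above left/right
shoulder).  The classifier is unsupervised and online: an incoming pattern
is matched against each learned gesture's synaptic weight vector by Pearson
correlation; below the novelty threshold a new target neuron is recruited,
otherwise the matched gesture's synapses are refined by the STDP rule.

Everything here runs on synthetic streams and patterns, so the front-end is
testable without camera hardware.  Coordinate convention for joint streams:
x lateral (positive rightward), y vertical (positive up), z depth (positive
away from the body, toward the camera).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .stdp import STDPParameters, ltd_factor, ltp_factor

HANDS = ("left_hand", "right_hand")
REQUIRED_JOINTS = ("left_hand", "right_hand", "left_shoulder", "right_shoulder")

#: the 20 feature neurons, in index order
FEATURE_NAMES = tuple(
    f"{hand}_{feat}"
    for hand in ("left", "right")
    for feat in ("up", "down", "left", "right", "toward_body", "away_from_body")
) + tuple(
    f"{hand}_{feat}"
    for hand in ("left", "right")
    for feat in (
        "overlaps_left_shoulder",
        "overlaps_right_shoulder",
        "above_left_shoulder",
        "above_right_shoulder",
    )
)
N_FEATURES = 20


def _pattern(*names: str) -> np.ndarray:
    p = np.zeros(N_FEATURES, dtype=np.uint8)
    for name in names:
        p[FEATURE_NAMES.index(name)] = 1
    return p


#: the twelve gesture prototypes.  The performer's neutral stance holds the
#: hands slightly in front of the body plane; shoulders sit on the plane, so
#: any motion ending on the body — drops to the sides, pulls to the torso,
#: reaches to a shoulder — also fires that hand's toward-body neuron, while
#: horizontal sweeps and pushes stay out in front.  The gesture definitions
#: prescribe the motion or end position, not the hand or path, so those are
#: documented conventions chosen to keep the twelve codes well separated:
#: the leftward sweep uses the left hand, a hand is placed above the
#: *opposite* shoulder by crossing over, and "both hands above both
#: shoulders" is the emphatic crossed-arms-overhead pose.
GESTURE_PROTOTYPES: Dict[str, np.ndarray] = {
    # both hands pulled in close to the body
    "A": _pattern("left_toward_body", "right_toward_body"),
    # single hand pushes away from the body
    "B": _pattern("right_away_from_body"),
    # single hand sweeps left (left hand, out in front)
    "C": _pattern("left_left"),
    # single hand sweeps right (right hand, out in front)
    "D": _pattern("right_right"),
    # single hand moves straight up, ending overhead
    "E": _pattern("right_up", "right_toward_body", "right_above_right_shoulder"),
    # single hand drops down to the side
    "F": _pattern("right_down", "right_toward_body"),
    # both hands drop down to the sides
    "G": _pattern(
        "left_down", "left_toward_body", "right_down", "right_toward_body"
    ),
    # single hand above the left shoulder (right hand crosses over)
    "H": _pattern(
        "right_up", "right_left", "right_toward_body", "right_above_left_shoulder"
    ),
    # single hand above the right shoulder (left hand crosses over)
    "I": _pattern(
        "left_up", "left_right", "left_toward_body", "left_above_right_shoulder"
    ),
    # both hands above both shoulders (arms crossed overhead)
    "J": _pattern(
        "left_up", "left_right", "left_toward_body", "left_above_right_shoulder",
        "right_up", "right_left", "right_toward_body", "right_above_left_shoulder",
    ),
    # left hand and left shoulder overlap
    "K": _pattern("left_up", "left_toward_body", "left_overlaps_left_shoulder"),
    # right hand and right shoulder overlap
    "L": _pattern("right_up", "right_toward_body", "right_overlaps_right_shoulder"),
}
GESTURE_LABELS = tuple(GESTURE_PROTOTYPES)


@dataclass(frozen=True)
class EncodingThresholds:
    """Geometric cutoffs, as fractions of the shoulder width."""

    displacement_fraction: float = 0.15
    overlap_fraction: float = 0.10
    above_fraction: float = 0.10


def _stream_to_arrays(stream) -> Dict[str, np.ndarray]:
    """Accept a {joint: (T, 3) array} dict or a long-form (frame, joint, x, y, z) DataFrame."""
    if isinstance(stream, pd.DataFrame):
        arrays = {}
        for joint, grp in stream.groupby("joint"):
            grp = grp.sort_values("frame")
            arrays[str(joint)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
        return arrays
    return {k: np.asarray(v, dtype=float) for k, v in stream.items()}


def encode_joint_stream(stream, thresholds: EncodingThresholds = EncodingThresholds()) -> np.ndarray:
    """Binary 20-feature activation for one joint-coordinate stream.

    Movement features fire when the hand's net displacement along the axis
    exceeds the displacement cutoff; position features fire from the last
    frame's geometry.  "Overlaps shoulder X" means within the overlap radius
    of that shoulder; "above shoulder X" means higher than it by the height
    cutoff *and* laterally over it (within half a shoulder width), so a hand
    raised over the left shoulder does not also read as above the right.
    """
    joints = _stream_to_arrays(stream)
    missing = [j for j in REQUIRED_JOINTS if j not in joints]
    if missing:
        raise ValueError(f"joint stream is missing required joints: {missing}")
    for name, coords in joints.items():
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise ValueError(f"joint {name!r} needs >= 2 frames of (x, y, z)")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"joint {name!r} has non-finite coordinates")

    shoulder_width = float(
        np.linalg.norm(joints["left_shoulder"][0] - joints["right_shoulder"][0])
    )
    if shoulder_width <= 0:
        raise ValueError("shoulders coincide; shoulder width must be positive")
    move_cut = thresholds.displacement_fraction * shoulder_width
    overlap_cut = thresholds.overlap_fraction * shoulder_width
    above_cut = thresholds.above_fraction * shoulder_width

    pattern = np.zeros(N_FEATURES, dtype=np.uint8)
    idx = 0
    for hand in HANDS:
        dx, dy, dz = joints[hand][-1] - joints[hand][0]
        pattern[idx + 0] = dy > move_cut          # up
        pattern[idx + 1] = dy < -move_cut         # down
        pattern[idx + 2] = dx < -move_cut         # left
        pattern[idx + 3] = dx > move_cut          # right
        pattern[idx + 4] = dz < -move_cut         # toward body
        pattern[idx + 5] = dz > move_cut          # away from body
        idx += 6
    for hand in HANDS:
        hand_end = joints[hand][-1]
        for shoulder in ("left_shoulder", "right_shoulder"):
            sh_end = joints[shoulder][-1]
            pattern[idx] = np.linalg.norm(hand_end - sh_end) < overlap_cut
            idx += 1
        for shoulder in ("left_shoulder", "right_shoulder"):
            sh_end = joints[shoulder][-1]
            over_it = abs(hand_end[0] - sh_end[0]) < shoulder_width / 2
            pattern[idx] = over_it and (hand_end[1] - sh_end[1]) > above_cut
            idx += 1
    return pattern


@dataclass
class ClassifierState:
    """Learned target neurons of the online gesture classifier.

    Each learned gesture owns one target neuron and a synaptic weight vector
    over the 20 feature neurons.  ``theta`` is the novelty threshold on the
    correlation coefficient: below it the pattern is declared a new gesture.

    ``batch_refractory`` reflects the training protocol, in which one batch
    presents each gesture exactly once: a target neuron that has already won
    within the current batch is briefly refractory and cannot win again until
    :meth:`begin_batch`.  This is what lets a gesture whose feature set
    contains another gesture's (both-hands-down vs single-hand-down) recruit
    its own neuron instead of being absorbed — a single sample cannot tell a
    superset prototype from a noisy variant, but the protocol can.
    """

    theta: float = 0.5
    initial_weight: float = 10.0
    weight_floor: float = 0.01
    weight_ceiling: float = 50.0
    stdp: STDPParameters = field(default_factory=STDPParameters)
    lag_ms: float = 10.0
    #: STDP pairings applied per presentation — feature neurons fire on every
    #: frame of a gesture, so one sample yields several pre/post pairings
    pairings_per_sample: int = 8
    batch_refractory: bool = False
    weights: List[np.ndarray] = field(default_factory=list)
    used_this_batch: set = field(default_factory=set)

    def __post_init__(self):
        if not (0.0 < self.theta < 1.0):
            raise ValueError("novelty threshold theta must lie in (0, 1)")

    @property
    def n_classes(self) -> int:
        return len(self.weights)

    def begin_batch(self) -> None:
        """Lift the within-batch refractoriness of all target neurons."""
        self.used_this_batch.clear()


def _correlation(pattern: np.ndarray, weight_vector: np.ndarray) -> float:
    p = pattern.astype(float)
    w = weight_vector.astype(float)
    if p.std() == 0 or w.std() == 0:
        return 0.0
    return float(np.corrcoef(p, w)[0, 1])


def classify_online(
    state: ClassifierState, pattern: np.ndarray
) -> Tuple[int, bool, ClassifierState]:
    """Match a pattern to a learned gesture, or recruit a new target neuron.

    The best-correlated class wins if its correlation reaches the novelty
    threshold; its synapses are then refined — co-active features potentiate,
    silent ones depress, both by the multiplicative STDP factors at the
    nominal lag.  Otherwise a new target neuron is recruited and its synapses
    are initialised from the pattern.  Mutates and returns ``state``.
    """
    pattern = np.asarray(pattern)
    if pattern.shape != (N_FEATURES,) or not np.all((pattern == 0) | (pattern == 1)):
        raise ValueError(f"pattern must be a binary vector of length {N_FEATURES}")
    if not pattern.any():
        raise ValueError("all-silent pattern: no gesture detected")

    up = ltp_factor(state.stdp, state.lag_ms) ** state.pairings_per_sample
    down = ltd_factor(state.stdp, state.lag_ms) ** state.pairings_per_sample
    eligible = [
        c for c in range(state.n_classes)
        if not (state.batch_refractory and c in state.used_this_batch)
    ]
    if eligible:
        corrs = [_correlation(pattern, state.weights[c]) for c in eligible]
        best = eligible[int(np.argmax(corrs))]
        if max(corrs) >= state.theta:
            w = state.weights[best]
            w *= np.where(pattern == 1, up, down)
            np.clip(w, state.weight_floor, state.weight_ceiling, out=w)
            state.used_this_batch.add(best)
            return best, False, state
    new_w = np.where(
        pattern == 1,
        min(state.initial_weight * up, state.weight_ceiling),
        state.weight_floor,
    )
    state.weights.append(new_w.astype(float))
    new_id = state.n_classes - 1
    state.used_this_batch.add(new_id)
    return new_id, True, state


def learn_batch(state: ClassifierState, patterns) -> List[Optional[int]]:
    """Online learning over one protocol batch (each gesture performed once).

    Because a batch presents twelve *distinct* gestures, target neurons
    compete across the whole batch: samples and neurons are paired one-to-one
    by descending correlation (greedy winner-take-all with lateral
    inhibition), so a noisy sample cannot steal another gesture's neuron from
    a better-matching sample.  Samples left unpaired above the novelty
    threshold recruit new target neurons; all-silent samples are skipped
    (``None`` in the returned assignment).  Matched neurons are refined and
    recruits initialised exactly as in :func:`classify_online`.
    """
    patterns = [np.asarray(p) for p in patterns]
    valid = [i for i, p in enumerate(patterns) if p.any()]
    assigned: Dict[int, int] = {}
    if state.n_classes and valid:
        pairs = sorted(
            (
                (_correlation(patterns[i], state.weights[c]), i, c)
                for i in valid
                for c in range(state.n_classes)
            ),
            key=lambda t: -t[0],
        )
        used_classes: set = set()
        for corr, i, c in pairs:
            if corr < state.theta:
                break
            if i in assigned or c in used_classes:
                continue
            assigned[i] = c
            used_classes.add(c)

    up = ltp_factor(state.stdp, state.lag_ms) ** state.pairings_per_sample
    down = ltd_factor(state.stdp, state.lag_ms) ** state.pairings_per_sample
    result: List[Optional[int]] = [None] * len(patterns)
    for i in valid:
        pattern = patterns[i]
        if i in assigned:
            c = assigned[i]
            w = state.weights[c]
            w *= np.where(pattern == 1, up, down)
            np.clip(w, state.weight_floor, state.weight_ceiling, out=w)
            result[i] = c
        else:
            new_w = np.where(
                pattern == 1,
                min(state.initial_weight * up, state.weight_ceiling),
                state.weight_floor,
            )
            state.weights.append(new_w.astype(float))
            result[i] = state.n_classes - 1
    return result


def classify_frozen(state: ClassifierState, pattern: np.ndarray) -> int:
    """Best-correlated learned class, without learning or recruitment."""
    if state.n_classes == 0:
        raise ValueError("classifier has no learned classes")
    corrs = [_correlation(np.asarray(pattern), w) for w in state.weights]
    return int(np.argmax(corrs))


def generate_synthetic_gestures(
    n_classes: int = 12,
    samples_per_class: int = 1,
    noise: float = 0.0,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Labelled synthetic feature patterns: prototypes with independent bit flips.

    Samples come out batch-ordered (one sample of each class per round), the
    layout of the online training protocol.  Deterministic for a fixed seed.
    Returns (patterns, labels) with labels as gesture letters.
    """
    if not (1 <= n_classes <= len(GESTURE_LABELS)):
        raise ValueError(f"n_classes must be in [1, {len(GESTURE_LABELS)}], got {n_classes}")
    if not (0.0 <= noise < 0.5):
        raise ValueError(f"flip noise must lie in [0, 0.5), got {noise}")
    rng = np.random.default_rng(seed)
    labels_round = GESTURE_LABELS[:n_classes]
    patterns, labels = [], []
    for _ in range(samples_per_class):
        for label in labels_round:
            proto = GESTURE_PROTOTYPES[label].copy()
            flips = rng.random(N_FEATURES) < noise
            patterns.append(np.where(flips, 1 - proto, proto).astype(np.uint8))
            labels.append(label)
    return np.array(patterns, dtype=np.uint8), np.array(labels)


def train_and_evaluate(
    n_batches: int,
    noise: float = 0.05,
    test_samples_per_class: int = 30,
    seed: Optional[int] = None,
    theta: float = 0.5,
) -> List[float]:
    """Run the online protocol and report test accuracy after each batch.

    A batch presents one (noisy) sample of each of the 12 gestures; the
    classifier learns unsupervised.  For scoring, each target neuron is
    labelled by the majority gesture among the training samples it matched
    (the standard way of scoring an unsupervised classifier); the held-out
    test set has ``test_samples_per_class`` noisy samples per gesture, and
    test classification is frozen (no learning, no recruitment).

    Noise can silence every feature of a sample; such no-gesture samples are
    invisible to a detector, so they are skipped in training and scored as
    errors in the test set.  Target neurons matched only once over the whole
    run never consolidated (their synapses encode a single noisy sample) and
    are excluded from test-time competition.
    """
    rng = np.random.default_rng(seed)
    train_patterns, train_labels = generate_synthetic_gestures(
        12, n_batches, noise, seed=int(rng.integers(2**31))
    )
    test_patterns, test_labels = generate_synthetic_gestures(
        12, test_samples_per_class, noise, seed=int(rng.integers(2**31))
    )
    state = ClassifierState(theta=theta)
    match_history: Dict[int, Counter] = defaultdict(Counter)
    accuracies = []
    for b in range(n_batches):
        batch = slice(b * 12, (b + 1) * 12)
        assignment = learn_batch(state, list(train_patterns[batch]))
        for cls, label in zip(assignment, train_labels[batch]):
            if cls is not None:
                match_history[cls][str(label)] += 1
        neuron_labels = {
            c: hist.most_common(1)[0][0] for c, hist in match_history.items()
        }
        min_matches = 2 if b >= 2 else 1
        consolidated = [
            c for c, hist in match_history.items() if sum(hist.values()) >= min_matches
        ] or list(neuron_labels)
        correct = 0
        for p, lbl in zip(test_patterns, test_labels):
            if not p.any():
                continue
            corrs = [_correlation(p, state.weights[c]) for c in consolidated]
            if neuron_labels[consolidated[int(np.argmax(corrs))]] == lbl:
                correct += 1
        accuracies.append(correct / len(test_labels))
    return accuracies


def synthetic_joint_stream(
    gesture: str,
    seed: Optional[int] = None,
    n_frames: int = 10,
    jitter: float = 0.01,
) -> Dict[str, np.ndarray]:
    """A jittered joint-coordinate stream realising one gesture's prototype.

    Shoulders sit 0.4 length units apart on the body plane (z = 0); the
    neutral hands hang slightly in front of it (twice the toward-body
    cutoff).  Prescribed displacements are twice the displacement cutoff,
    and placement targets lie on the plane, so the intended features fire
    unambiguously.
    """
    if gesture not in GESTURE_PROTOTYPES:
        raise ValueError(f"unknown gesture {gesture!r}; expected one of {GESTURE_LABELS}")
    rng = np.random.default_rng(seed)
    width = 0.4
    z0 = 2 * 0.15 * width  # neutral forward offset of the hands
    base = {
        "left_shoulder": np.array([-width / 2, 1.4, 0.0]),
        "right_shoulder": np.array([width / 2, 1.4, 0.0]),
        "left_hand": np.array([-width / 2, 0.9, z0]),
        "right_hand": np.array([width / 2, 0.9, z0]),
    }
    move = 2 * 0.15 * width  # 2x displacement cutoff
    displacement = {j: np.zeros(3) for j in base}
    target: Dict[str, np.ndarray] = {}
    axis = {"up": (1, +1), "down": (1, -1), "left": (0, -1), "right": (0, +1),
            "toward_body": (2, -1), "away_from_body": (2, +1)}
    proto = GESTURE_PROTOTYPES[gesture]
    for f in np.where(proto == 1)[0]:
        name = FEATURE_NAMES[f]
        hand = "left_hand" if name.startswith("left_") else "right_hand"
        feat = name.split("_", 1)[1]
        if feat.startswith("overlaps_"):
            shoulder = feat.removeprefix("overlaps_")
            target[hand] = base[shoulder].copy()
        elif feat.startswith("above_"):
            shoulder = feat.removeprefix("above_")
            target[hand] = base[shoulder] + np.array([0.0, 2 * 0.10 * width, 0.0])
        elif feat in axis:
            ax, sign = axis[feat]
            displacement[hand][ax] += sign * move
    # a placement target realises the hand's movement features itself
    for hand in target:
        displacement[hand][:] = 0.0

    stream = {}
    t = np.linspace(0.0, 1.0, n_frames)[:, None]
    for joint, start in base.items():
        end = target.get(joint, start + displacement[joint])
        path = start + t * (end - start)
        path = path + rng.normal(0.0, jitter * width, size=path.shape)
        path[0], path[-1] = start, end  # endpoints exact: net displacement prescribed
        stream[joint] = path
    return stream


# --- abstract trajectory code -------------------------------------------------

#: the six trajectory views and the action each commands
TRAJECTORY_STATES = (
    "line_centered",      # move forward
    "no_line",            # move backward
    "line_left",          # move left
    "line_right",         # move right
    "line_turns_left",    # turn left
    "line_turns_right",   # turn right
)
TRAJECTORY_ACTIONS = (
    "move_forward", "move_backward", "move_left",
    "move_right", "turn_left", "turn_right",
)


def encode_trajectory_state(label: str) -> np.ndarray:
    """One-hot 6-neuron activation for a trajectory view; the index doubles
    as the state index fed to the intention circuit."""
    if label not in TRAJECTORY_STATES:
        raise ValueError(f"unknown trajectory state {label!r}; expected one of {TRAJECTORY_STATES}")
    code = np.zeros(len(TRAJECTORY_STATES), dtype=np.uint8)
    code[TRAJECTORY_STATES.index(label)] = 1
    return code


def generate_trajectory_sequence(n: int, seed: Optional[int] = None) -> List[str]:
    """A random sequence of trajectory views, e.g. for driving the circuit."""
    rng = np.random.default_rng(seed)
    return [TRAJECTORY_STATES[i] for i in rng.integers(0, len(TRAJECTORY_STATES), size=n)]


def patterns_to_csv(patterns: np.ndarray, labels: np.ndarray, path) -> None:
    """One row per sample: the 20 feature columns plus the gesture label."""
    frame = pd.DataFrame(patterns, columns=list(FEATURE_NAMES))
    frame["label"] = labels
    frame.to_csv(path, index=False)


def patterns_from_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path)
    labels = frame.pop("label").to_numpy()
    return frame.to_numpy(dtype=np.uint8), labels
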