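"""The interaction protocol: predict, receive right/wrong feedback, update.

One *interaction* is one (prediction, feedback) pair.  Training a rule set
presents each state in turn and repeats it until the model predicts that
state's intention correctly, then moves on; training is complete when every
state was predicted correctly at its most recent presentation.  Under the
circuit's update semantics (potentiate the earned synapse, depress the earned
intention for every other state, depress only the tried synapse on a wrong
guess) the cost of a state equals the rank of its correct intention among the
intentions not yet claimed by earlier states — which is what bounds the total
between N and N(N+1)/2 interactions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .config import RunConfiguration
from .network import (
    BrainNetwork,
    PlasticityEvent,
    RewardValence,
    TrialRecord,
    build_network,
    encode_state,
    forward_pass,
    route_reward,
)
from .stdp import apply_multiplicative_update, stdp_delta


@dataclass(frozen=True)
class RuleSet:
    """A bijective state→intention mapping (0-based internally).

    ``mapping[i]`` is the intention the user wants predicted for state ``i``.
    User-facing I/O is 1-based ("intention 1") via :meth:`from_one_based` /
    :meth:`to_one_based`.
    """

    mapping: tuple

    def __post_init__(self):
        m = tuple(int(x) for x in self.mapping)
        if sorted(m) != list(range(len(m))):
            raise ValueError(f"rule must be a permutation of 0..N-1, got {m}")
        object.__setattr__(self, "mapping", m)

    @property
    def n(self) -> int:
        return len(self.mapping)

    def __getitem__(self, state: int) -> int:
        return self.mapping[state]

    @classmethod
    def identity(cls, n: int) -> "RuleSet":
        return cls(tuple(range(n)))

    @classmethod
    def reversal(cls, n: int) -> "RuleSet":
        """The worst-case rule under the ascending candidate order."""
        return cls(tuple(range(n - 1, -1, -1)))

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "RuleSet":
        return cls(tuple(int(x) for x in rng.permutation(n)))

    @classmethod
    def from_one_based(cls, labels: Sequence[int]) -> "RuleSet":
        return cls(tuple(int(x) - 1 for x in labels))

    def to_one_based(self) -> tuple:
        return tuple(x + 1 for x in self.mapping)


@dataclass
class InteractionRecord:
    """One trial of the protocol."""

    trial: int
    state: int
    predicted: int
    feedback_positive: bool
    events: List[PlasticityEvent] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["events"] = [
            {"state": e["state"], "intention": e["intention"], "delta_t_ms": e["delta_t_ms"]}
            for e in d["events"]
        ]
        return json.dumps(d)


@dataclass
class TrainingResult:
    """Outcome of training a network on one rule set."""

    interactions: int
    weights: np.ndarray
    transcript: List[InteractionRecord]
    per_state_interactions: dict
    #: for relearning runs: wrong predictions of the *old* intention per state
    abandonment_counts: dict = field(default_factory=dict)

    def write_transcript(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.transcript:
                fh.write(rec.to_json() + "\n")


def predict_intention(network: BrainNetwork, state_index: int) -> tuple:
    """Run one forward pass for a state; no weights are changed."""
    drive = encode_state(network, state_index)
    return forward_pass(network, drive)


def apply_feedback(
    network: BrainNetwork, record: TrialRecord, positive: bool
) -> List[PlasticityEvent]:
    """Convert feedback into STDP events and apply them to the plastic matrix.

    Each plastic synapse is updated at most once per feedback event (one
    spike pair per trial).  Returns the applied events.
    """
    valence = RewardValence.POSITIVE if positive else RewardValence.NEGATIVE
    events = route_reward(network, valence, record)
    floor = network.config.weight_floor
    for ev in events:
        delta = stdp_delta(ev.delta_t_ms, network.config.stdp)
        apply_multiplicative_update(network.weights, ev.state, ev.intention, delta, floor)
    network.bump_version()
    return events


def _presentation_order(
    n: int, policy: str, rng: Optional[np.random.Generator]
) -> List[int]:
    if policy == "sequential":
        return list(range(n))
    if policy == "shuffled":
        if rng is None:
            raise ValueError("shuffled presentation order requires an rng")
        return [int(x) for x in rng.permutation(n)]
    raise ValueError(f"unknown presentation order policy: {policy!r}")


def train_rule_set(
    rule: RuleSet,
    network: Optional[BrainNetwork] = None,
    config: Optional[RunConfiguration] = None,
    order: Optional[Sequence[int]] = None,
    rng: Optional[np.random.Generator] = None,
    _old_rule: Optional[RuleSet] = None,
) -> TrainingResult:
    """Train a (fresh or given) network on ``rule`` to criterion.

    States are presented in ``order`` (default: the configured policy), each
    repeated until predicted correctly, with truthful right/wrong feedback
    after every prediction.  The interaction count is the number of feedback
    events issued.  A guard trips if training exceeds what any functioning
    update rule could need, signalling broken semantics rather than looping.
    """
    n = rule.n
    if network is None:
        config = config or RunConfiguration(n_intentions=n)
        network = build_network(n, config)
    elif network.n != n:
        raise ValueError(f"network has {network.n} intentions, rule has {n}")
    if order is None:
        order = _presentation_order(n, network.config.presentation_order, rng)
    order = list(order)
    if sorted(order) != list(range(n)):
        raise ValueError("presentation order must cover every state exactly once")

    # relearning can spend extra trials abandoning the old rule
    guard = n * (n + 1) if _old_rule is None else 3 * n * (n + 1)
    transcript: List[InteractionRecord] = []
    per_state = {s: 0 for s in order}
    abandonment = {s: 0 for s in order}
    trial = 0
    for s in order:
        while True:
            trial += 1
            if trial > guard:
                raise RuntimeError(
                    f"training did not terminate within {guard} trials; "
                    "update semantics are broken"
                )
            predicted, rec = predict_intention(network, s)
            correct = predicted == rule[s]
            events = apply_feedback(network, rec, positive=correct)
            transcript.append(
                InteractionRecord(trial, s, predicted, correct, events)
            )
            per_state[s] += 1
            if _old_rule is not None and not correct and predicted == _old_rule[s]:
                abandonment[s] += 1
            if correct:
                break

    final_argmax = tuple(int(j) for j in np.argmax(network.weights, axis=1))
    if final_argmax != rule.mapping:
        raise RuntimeError(
            f"training ended but weights do not encode the rule: "
            f"argmax {final_argmax} vs rule {rule.mapping}"
        )
    return TrainingResult(
        interactions=trial,
        weights=network.weights.copy(),
        transcript=transcript,
        per_state_interactions=per_state,
        abandonment_counts=abandonment if _old_rule is not None else {},
    )


def relearn_after_rule_change(
    network: BrainNetwork,
    old_rule: RuleSet,
    new_rule: RuleSet,
    order: Optional[Sequence[int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrainingResult:
    """Continue training a converged network after the user changes some rules.

    States whose mapping did not change are predicted correctly at their first
    post-change presentation (cost 1); changed states first abandon the old
    intention (a few wrong predictions shrink its weight below the field)
    and then learn the new one.  Abandonment counts are reported per state.
    """
    if old_rule.n != new_rule.n or network.n != new_rule.n:
        raise ValueError("old rule, new rule and network must share the same N")
    return train_rule_set(
        new_rule, network=network, order=order, rng=rng, _old_rule=old_rule
    )
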