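"""Training-cost analysis: the elimination counting model, the tabular
Q-learning baseline, and statistics over the whole rule space.

For a rule set (a permutation π of N intentions) trained state-by-state with
truthful feedback, the spiking circuit's interaction count reduces to an
elimination process: the cost of state i is the rank of π(i) among the
intentions no earlier state has claimed, because a learned intention's column
has been depressed for every other state and is never tried again.  Summed
over states this equals N plus the number of inversions of π, so over all N!
rules the counts follow the (symmetric) Mahonian distribution shifted by N:

    min = N,   max = N(N+1)/2,   mode = mean = (N + N(N+1)/2) / 2.

The tabular Q-learning baseline has no cross-state elimination: each state
independently tries intentions in index order until rewarded, costing
1 + π(i), for a rule-independent total of N(N+1)/2.  The advantage of the
circuit over the baseline is therefore

    N(N+1)/2 − (N + N(N+1)/2)/2 = (N² − N)/4.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .interaction import RuleSet

EXHAUSTIVE_LIMIT = 10


@dataclass(frozen=True)
class TrainingDistribution:
    """Statistics of interaction counts over a set of rules at a given N."""

    n: int
    n_rules: int
    min: int
    max: int
    mode: float  # ties averaged


@dataclass(frozen=True)
class ImprovementReport:
    """Training advantage of the circuit over the Q-learning baseline."""

    n: int
    train_q: float
    train_biip: float  # modal count of the brain-inspired model
    train_improve: float


def rank_sum_count(rule: RuleSet, candidate_order: Optional[Sequence[int]] = None) -> int:
    """Interaction count of the elimination model for one rule.

    States are processed in index order.  For each state, candidate
    intentions are tried in ``candidate_order`` (default ascending index),
    skipping intentions already claimed by earlier states; the cost is the
    number of tries including the correct one.  This is the abstract
    equivalent of the spiking loop's behaviour.
    """
    n = rule.n
    order = list(candidate_order) if candidate_order is not None else list(range(n))
    if sorted(order) != list(range(n)):
        raise ValueError("candidate order must be a permutation of all intentions")
    learned: set = set()
    total = 0
    for state in range(n):
        target = rule[state]
        for candidate in order:
            if candidate in learned:
                continue
            total += 1
            if candidate == target:
                break
        learned.add(target)
    return total


def q_learning_count(rule: RuleSet) -> int:
    """Interaction count of the reconstructed tabular Q-learning baseline.

    Zero-initialised Q table, greedy selection with lowest-index tie-break,
    reward +1/−1, learning rate 1, no exploration, states independent.  The
    count is 1 + π(i) per state, hence N(N+1)/2 for every rule.
    """
    n = rule.n
    total = 0
    for state in range(n):
        q = np.zeros(n)
        while True:
            action = int(np.argmax(q))  # lowest index on ties
            total += 1
            reward = 1.0 if action == rule[state] else -1.0
            q[action] += 1.0 * (reward - q[action])
            if reward > 0:
                break
    return total


def _all_rule_counts(n: int) -> np.ndarray:
    """Elimination counts for all N! rules, vectorised.

    Uses the identity count(π) = N + inversions(π): the cost of state i is
    1 + π(i) − #{k < i : π(k) < π(i)} (candidates below π(i) not yet claimed),
    which telescopes to N + #inversions.  Equality with
    :func:`rank_sum_count` is asserted exhaustively in the test suite.
    """
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    counts = np.full(perms.shape[0], n, dtype=np.int64)
    for i in range(n):
        for k in range(i + 1, n):
            counts += perms[:, i] > perms[:, k]
    return counts


def _sampled_rule_counts(n: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.argsort(rng.random((n_samples, n)), axis=1)
    counts = np.full(n_samples, n, dtype=np.int64)
    for i in range(n):
        for k in range(i + 1, n):
            counts += perms[:, i] > perms[:, k]
    return counts


def mode_tie_mean(counts: Iterable[int]) -> float:
    """Mode of integer counts; when several values tie, their mean."""
    values, freq = np.unique(np.asarray(list(counts), dtype=np.int64), return_counts=True)
    tied = values[freq == freq.max()]
    return float(tied.mean())


def distribution_over_rules(
    n: int,
    method: str = "exhaustive",
    seed: Optional[int] = None,
    n_samples: int = 100_000,
) -> TrainingDistribution:
    """Interaction-count statistics over the rule space at a given N.

    ``exhaustive`` enumerates all N! rules (refused above N=10, where the
    closed forms plus seeded sampling are authoritative); ``sampled`` draws
    ``n_samples`` rules uniformly with the given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "exhaustive":
        if n > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration refused for n={n} (> {EXHAUSTIVE_LIMIT}); "
                "use method='sampled' with a seed"
            )
        counts = _all_rule_counts(n)
        n_rules = math.factorial(n)
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        counts = _sampled_rule_counts(n, n_samples, rng)
        n_rules = n_samples
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrainingDistribution(
        n=n,
        n_rules=n_rules,
        min=int(counts.min()),
        max=int(counts.max()),
        mode=mode_tie_mean(counts),
    )


# closed forms implied by the elimination model's symmetric count distribution
def q_learning_closed_form(n: int) -> int:
    return n * (n + 1) // 2


def min_closed_form(n: int) -> int:
    return n


def max_closed_form(n: int) -> int:
    return n * (n + 1) // 2


def mode_closed_form(n: int) -> float:
    return (n + n * (n + 1) / 2) / 2


def improvement_formula(n: int) -> ImprovementReport:
    """Training-count advantage over Q-learning: (N² − N)/4, exactly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    train_q = float(q_learning_closed_form(n))
    train_biip = mode_closed_form(n)
    return ImprovementReport(
        n=n, train_q=train_q, train_biip=train_biip, train_improve=train_q - train_biip
    )


TABLE_ROWS = (
    "Number of rules",
    "Q-learning method",
    "The proposed model (Mode)",
    "The proposed model (Min)",
    "The proposed model (Max)",
)


def training_cost_table(
    n_values: Sequence[int] = tuple(range(1, 10)),
    method: str = "exhaustive",
    seed: Optional[int] = None,
    n_samples: int = 100_000,
) -> pd.DataFrame:
    """Per-N comparison table: rule count, Q-learning cost, and the circuit's
    mode/min/max over rules (exhaustive by default, sampled beyond N=10)."""
    cols = {}
    for n in n_values:
        dist = distribution_over_rules(n, method=method, seed=seed, n_samples=n_samples)
        q = q_learning_count(RuleSet.identity(n))
        cols[n] = {
            TABLE_ROWS[0]: math.factorial(n),
            TABLE_ROWS[1]: q,
            TABLE_ROWS[2]: dist.mode,
            TABLE_ROWS[3]: dist.min,
            TABLE_ROWS[4]: dist.max,
        }
    frame = pd.DataFrame(cols)
    frame.index.name = "Number of intentions"
    return frame.loc[list(TABLE_ROWS)]


def extended_comparison(n_max: int = 50) -> dict:
    """Closed-form Q-learning vs modal circuit cost for N = 1..n_max."""
    report = {}
    for n in range(1, n_max + 1):
        imp = improvement_formula(n)
        report[n] = {
            "q_learning": imp.train_q,
            "proposed_mode": imp.train_biip,
            "improvement": imp.train_improve,
        }
    return report
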