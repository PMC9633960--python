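"""Spike-timing-dependent plasticity and the ratio-based weight update.

The weight change for one pre/post spike pair depends only on the timing
difference Δt = t_pre(DLPFC) − t_post(BG):

    Δw = A+ · exp(Δt / τ+)   if Δt < 0   (pre before post: LTP)
    Δw = A− · exp(Δt / τ−)   if Δt ≥ 0   (post before pre: LTD)

with the constants fitted to biological pairing data: A+ = 0.777,
A− = −0.237, τ+ = 16.8 ms, τ− = −33.7 ms (τ− is negative as printed, so the
LTD branch also decays with |Δt|).

Weights are updated as a *ratio* of their current value,
W ← W + W·Δw = W·(1 + Δw), which is what lets an already-learned rule be
forgotten in a handful of feedback events when the user changes it.
A small positive floor prevents the multiplicative rule from reaching an
absorbing zero it could never regrow from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class STDPParameters:
    """Learning rates and time constants of the pair-based STDP rule."""

    a_plus: float = 0.777
    a_minus: float = -0.237
    tau_plus: float = 16.8   # ms
    tau_minus: float = -33.7  # ms (negative as printed)

    def __post_init__(self):
        if self.tau_plus <= 0:
            raise ValueError("tau_plus must be positive")
        if self.tau_minus >= 0:
            raise ValueError("tau_minus must be negative")


DEFAULT_STDP = STDPParameters()

#: nominal pre/post lag (ms) assigned to reward-routed spike pairs.  The
#: medial-OFC pathway fires DLPFC before striatum (Δt = −LAG, LTP); the
#: lateral-OFC pathway fires striatum before DLPFC (Δt = +LAG, LTD).
NOMINAL_LAG_MS = 10.0


def stdp_delta(delta_t: float, params: STDPParameters = DEFAULT_STDP) -> float:
    """Weight-change ratio for one spike pair at timing difference ``delta_t`` (ms).

    Total function: positive exactly when ``delta_t < 0`` (presynaptic DLPFC
    spike leads), negative otherwise.
    """
    if delta_t < 0:
        return params.a_plus * math.exp(delta_t / params.tau_plus)
    return params.a_minus * math.exp(delta_t / params.tau_minus)


def apply_multiplicative_update(
    weights: np.ndarray,
    i: int,
    j: int,
    delta_w: float,
    floor: float = 0.0,
) -> np.ndarray:
    """Apply W[i,j] ← W[i,j]·(1 + Δw), clamped below at ``floor``; in place.

    ``delta_w`` must exceed −1: a factor of zero (or a sign flip) would
    annihilate the synapse permanently under a multiplicative rule.
    """
    if delta_w <= -1.0:
        raise ValueError(f"delta_w must be > -1 to preserve positivity, got {delta_w}")
    n_rows, n_cols = weights.shape
    if not (0 <= i < n_rows and 0 <= j < n_cols):
        raise IndexError(f"synapse index ({i}, {j}) out of range for {weights.shape}")
    weights[i, j] = max(weights[i, j] * (1.0 + delta_w), floor)
    return weights


def ltp_factor(params: STDPParameters = DEFAULT_STDP, lag_ms: float = NOMINAL_LAG_MS) -> float:
    """Multiplier 1 + Δw(−lag) applied on a potentiation event."""
    return 1.0 + stdp_delta(-lag_ms, params)


def ltd_factor(params: STDPParameters = DEFAULT_STDP, lag_ms: float = NOMINAL_LAG_MS) -> float:
    """Multiplier 1 + Δw(+lag) applied on a depression event."""
    return 1.0 + stdp_delta(+lag_ms, params)


def weights_to_csv(weights: np.ndarray, path) -> None:
    """Write a weight matrix as CSV: rows = state categories, columns = intentions.

    Labels are 1-based to match the user-facing "intention 1" convention.
    """
    n_rows, n_cols = weights.shape
    frame = pd.DataFrame(
        weights,
        index=[f"state_{i + 1}" for i in range(n_rows)],
        columns=[f"intention_{j + 1}" for j in range(n_cols)],
    )
    frame.to_csv(path, index_label="state")


def weights_from_csv(path) -> np.ndarray:
    frame = pd.read_csv(path, index_col=0)
    return frame.to_numpy(dtype=float)
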