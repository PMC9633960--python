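"""Izhikevich neuron dynamics, synaptic input and winner-take-all competition.

The two-variable Izhikevich model drives every region of the intention
circuit.  Membrane potential ``v`` and recovery variable ``u`` evolve as

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with the after-spike reset ``v <- c``, ``u <- u + d`` applied whenever the
advanced ``v`` reaches 30 mV.  The reset constants are shared by all regions
(``c = -65``, ``d = 8``); the ``(a, b)`` pair distinguishes the two striatal
populations from every other region.

Integration is forward Euler with a 0.5 ms step, the standard published
practice for this neuron model.  Both update terms are evaluated on the
pre-step state (synchronous Euler); resets are applied at step end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

SPIKE_THRESHOLD_MV = 30.0

#: default integration step (ms)
DEFAULT_DT_MS = 0.5


class NumericalDivergenceError(FloatingPointError):
    """Raised when a neuron state or input is no longer finite."""


@dataclass(frozen=True)
class NeuronParameters:
    """Izhikevich parameter quadruple.

    a : recovery time scale (dimensionless)
    b : recovery sensitivity to ``v`` (dimensionless)
    c : reset potential, mV
    d : after-spike recovery increment
    """

    a: float
    b: float
    c: float = -65.0
    d: float = 8.0


#: striatal D1 ("Go") population
STRD1_PARAMS = NeuronParameters(a=0.01, b=0.01)
#: striatal D2 ("NoGo") population
STRD2_PARAMS = NeuronParameters(a=0.1, b=0.5)
#: every non-striatal region (DLPFC, BG output, thalamus, PMC, OFC, ...)
REGULAR_PARAMS = NeuronParameters(a=0.02, b=0.6)


@dataclass
class NeuronState:
    """Membrane potential ``v`` (mV) and recovery variable ``u``."""

    v: float
    u: float


def resting_state(params: NeuronParameters) -> NeuronState:
    """Initial condition used throughout: v = -65 mV, u = b * v."""
    return NeuronState(v=-65.0, u=params.b * -65.0)


def step_neuron(
    state: NeuronState,
    params: NeuronParameters,
    input_current: float,
    dt: float = DEFAULT_DT_MS,
) -> Tuple[NeuronState, bool]:
    """Advance one neuron by one Euler step; apply the reset if it fired.

    Returns the post-step state and a firing flag.  When the flag is true
    the returned state is the *reset* state (v = c, u incremented by d);
    the threshold-crossing voltage is not retained here — population-level
    code keeps it for winner-take-all comparison.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(input_current)):
        raise NumericalDivergenceError(
            f"non-finite neuron step: v={state.v}, u={state.u}, I={input_current}"
        )
    dv = 0.04 * state.v * state.v + 5.0 * state.v + 140.0 - state.u + input_current
    du = params.a * (params.b * state.v - state.u)
    v = state.v + dt * dv
    u = state.u + dt * du
    if not (math.isfinite(v) and math.isfinite(u)):
        raise NumericalDivergenceError(f"neuron state diverged: v={v}, u={u}")
    if v >= SPIKE_THRESHOLD_MV:
        return NeuronState(v=params.c, u=u + params.d), True
    return NeuronState(v=v, u=u), False


class IzhikevichPopulation:
    """A vectorised population of identical-parameter Izhikevich neurons.

    ``step(I)`` advances all neurons synchronously and returns the boolean
    spike vector; ``last_crossing_v`` holds the pre-reset membrane voltage
    of the neurons that fired on the most recent step (NaN elsewhere), which
    is what the winner-take-all rule compares.
    """

    def __init__(self, n: int, params: NeuronParameters, dt: float = DEFAULT_DT_MS):
        if n < 1:
            raise ValueError(f"population size must be >= 1, got {n}")
        self.n = n
        self.params = params
        self.dt = dt
        self.v = np.full(n, -65.0)
        self.u = np.full(n, params.b * -65.0)
        self.last_crossing_v = np.full(n, np.nan)

    def step(self, input_current: np.ndarray | float) -> np.ndarray:
        I = np.broadcast_to(np.asarray(input_current, dtype=float), (self.n,))
        if not np.all(np.isfinite(I)):
            raise NumericalDivergenceError(f"non-finite input current: {I}")
        dv = 0.04 * self.v * self.v + 5.0 * self.v + 140.0 - self.u + I
        du = self.params.a * (self.params.b * self.v - self.u)
        self.v = self.v + self.dt * dv
        self.u = self.u + self.dt * du
        if not (np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.u))):
            raise NumericalDivergenceError("population state diverged")
        fired = self.v >= SPIKE_THRESHOLD_MV
        self.last_crossing_v = np.where(fired, self.v, np.nan)
        if fired.any():
            self.v = np.where(fired, self.params.c, self.v)
            self.u = np.where(fired, self.u + self.params.d, self.u)
        return fired


def synaptic_input(weights, spikes):
    """Current delivered to target neurons: elementwise W x O, summed over sources.

    ``weights`` may be a scalar, a source vector (targets receive the scalar
    sum), or a (n_source, n_target) matrix.  ``spikes`` is the binary output
    vector of the source population.  No presynaptic spike means zero current.
    """
    W = np.asarray(weights, dtype=float)
    O = np.asarray(spikes, dtype=float)
    if not np.all(np.isfinite(W)) or np.any(W < 0):
        raise ValueError("synaptic weights must be finite and non-negative")
    if not np.all((O == 0) | (O == 1)):
        raise ValueError("spike vector must be binary")
    if W.ndim <= 1:
        if W.shape != O.shape:
            raise ValueError(f"weight/spike shape mismatch: {W.shape} vs {O.shape}")
        return float(np.sum(W * O)) if W.ndim == 1 else float(W * O)
    if W.ndim == 2:
        if O.shape != (W.shape[0],):
            raise ValueError(f"weight/spike shape mismatch: {W.shape} vs {O.shape}")
        return O @ W
    raise ValueError(f"weights must be at most 2-D, got ndim={W.ndim}")


def winner_take_all(
    candidates: Iterable[Tuple[int, float]],
) -> Optional[int]:
    """Resolve simultaneous firing: the largest-voltage neuron survives.

    Exact voltage ties go to the lowest neuron index, which keeps the whole
    pipeline deterministic.  An empty candidate set is not an error — it
    returns ``None`` ("no spike this step").
    """
    best_id: Optional[int] = None
    best_v = -math.inf
    for neuron_id, v in candidates:
        if v > best_v or (v == best_v and (best_id is None or neuron_id < best_id)):
            best_id = neuron_id
            best_v = v
    return best_id
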