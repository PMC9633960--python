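"""The intention-prediction circuit: region topology, state encoding, forward
pass and reward routing.

The circuit mirrors the cortico–basal-ganglia reinforcement loop:

* DLPFC represents the discrete visual state; one N-neuron row per category.
* The basal ganglia (striatal D1/D2 populations feeding a BG output stage)
  select one intention by winner-take-all over the plastic DLPFC→BG weights.
* Thalamus relays the selection to PMC (motor output) and to OFC.
* SNc/VTA gates the user's feedback: positive feedback opens the medial-OFC
  (MOFC) pathway, which potentiates the chosen (state, intention) synapse and
  — via its inhibition of lateral OFC (LOFC) — depresses the chosen intention's
  synapses from every *other* state, reserving that intention for the state
  that earned it.  Negative feedback drives the LOFC pathway alone, which
  depresses only the chosen synapse.

The single plastic edge is DLPFC→BG; every other connection is a fixed-weight
relay.  Plasticity events are emitted as (state, intention, Δt) triples with
the nominal ±lag timing the two OFC pathways impose (DLPFC leads striatum on
the MOFC route, trails it on the LOFC route).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Tuple

import numpy as np

from .config import RunConfiguration
from .izhikevich import (
    REGULAR_PARAMS,
    STRD1_PARAMS,
    STRD2_PARAMS,
    IzhikevichPopulation,
    NeuronParameters,
    NeuronState,
    step_neuron,
    synaptic_input,
    winner_take_all,
)

REGION_NAMES = (
    "DLPFC",
    "StrD1",
    "StrD2",
    "BG-output",
    "Thalamus",
    "PMC",
    "SNc/VTA",
    "OFC_1",
    "OFC_2",
    "MOFC",
    "LOFC",
)

REGION_PARAMS = {name: REGULAR_PARAMS for name in REGION_NAMES}
REGION_PARAMS["StrD1"] = STRD1_PARAMS
REGION_PARAMS["StrD2"] = STRD2_PARAMS

#: (source, target, excitatory?) — the fixed-weight relays of the circuit
FIXED_EDGES = (
    ("DLPFC", "StrD1", True),
    ("DLPFC", "StrD2", True),
    ("StrD1", "BG-output", True),
    ("StrD2", "BG-output", True),
    ("BG-output", "Thalamus", True),
    ("Thalamus", "PMC", True),
    ("Thalamus", "OFC_1", True),
    ("PMC", "SNc/VTA", True),
    ("SNc/VTA", "OFC_2", True),
    ("OFC_1", "MOFC", True),
    ("OFC_2", "LOFC", True),
    ("MOFC", "StrD1", True),
    ("MOFC", "DLPFC", True),
    ("MOFC", "LOFC", False),  # inhibitory: positive reward vetoes LTD on the earning state
    ("LOFC", "StrD2", True),
    ("LOFC", "DLPFC", True),
)


class NoSpikeError(RuntimeError):
    """The BG stage produced no spike within the trial window."""


class RewardValence(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class RegionSpec:
    name: str
    shape: Tuple[int, int]
    params: NeuronParameters


@dataclass(frozen=True)
class PlasticityEvent:
    """One STDP pairing on the plastic matrix: synapse (state, intention) at lag Δt."""

    state: int
    intention: int
    delta_t_ms: float

    @property
    def is_ltp(self) -> bool:
        return self.delta_t_ms < 0


@dataclass
class TrialRecord:
    """Spike bookkeeping of one prediction trial, consumed by reward routing."""

    state: int
    intention: int
    t_dlpfc_ms: float
    t_bg_ms: float
    t_pmc_ms: Optional[float]
    weights_version: int


@dataclass
class BrainNetwork:
    """Topology + plastic weight matrix + configuration for one model instance."""

    n: int
    regions: Tuple[RegionSpec, ...]
    fixed_edges: Tuple[Tuple[str, str, bool], ...]
    weights: np.ndarray
    config: RunConfiguration
    weights_version: int = 0

    @property
    def plastic_edge(self) -> Tuple[str, str]:
        return ("DLPFC", "BG-output")

    def bump_version(self) -> None:
        self.weights_version += 1

    def topology_json(self) -> str:
        """Structural summary (regions, shapes, edges, plasticity flags)."""
        edges = [
            {"source": s, "target": t, "excitatory": exc,
             "weight": self.config.fixed_edge_weight, "plastic": False}
            for s, t, exc in self.fixed_edges
        ]
        edges.append(
            {"source": "DLPFC", "target": "BG-output", "excitatory": True,
             "weight": None, "plastic": True}
        )
        payload = {
            "n_intentions": self.n,
            "regions": [
                {"name": r.name, "shape": list(r.shape)} for r in self.regions
            ],
            "edges": edges,
        }
        return json.dumps(payload, indent=2)


def build_network(
    n_intentions: int, config: Optional[RunConfiguration] = None
) -> BrainNetwork:
    """Construct the circuit for ``n_intentions`` state/intention categories.

    Every region is an N×N grid except PMC (1×N).  The plastic DLPFC→BG
    weights start uniform at the configured initial weight, so the first
    prediction for any state is intention 1 by the deterministic tie-break.
    """
    if n_intentions < 1:
        raise ValueError(f"n_intentions must be >= 1, got {n_intentions}")
    config = config or RunConfiguration(n_intentions=n_intentions)
    n = n_intentions
    regions = tuple(
        RegionSpec(
            name=name,
            shape=(1, n) if name == "PMC" else (n, n),
            params=REGION_PARAMS[name],
        )
        for name in REGION_NAMES
    )
    weights = np.full((n, n), float(config.initial_weight))
    return BrainNetwork(
        n=n,
        regions=regions,
        fixed_edges=FIXED_EDGES,
        weights=weights,
        config=config,
    )


def encode_state(network: BrainNetwork, state_index: int) -> np.ndarray:
    """Drive pattern for one visual category: constant current into its DLPFC row.

    All neurons representing the category are activated; every other DLPFC
    neuron receives zero drive (and stays quiescent for the trial).
    """
    n = network.n
    if not (0 <= state_index < n):
        raise ValueError(f"state_index {state_index} out of range [0, {n})")
    drive = np.zeros((n, n))
    drive[state_index, :] = network.config.drive_current
    return drive


def forward_pass(
    network: BrainNetwork, drive: np.ndarray
) -> Tuple[int, TrialRecord]:
    """Simulate one trial window and return the selected intention.

    The driven DLPFC rows spike under their constant current; each volley
    delivers current W[i, j] to BG intention-neuron j (Eq. I = W·O at the
    category level, the row's neurons firing in lockstep).  The first BG
    firing step is resolved by winner-take-all on membrane voltage; the
    winner's spike is then relayed through thalamus to PMC.  Undriven DLPFC
    rows are held quiescent — the printed recovery-sensitivity parameters
    leave the neuron without a stable rest, so activation is gated by the
    visual drive (see the methods note).
    """
    cfg = network.config
    n = network.n
    drive = np.asarray(drive, dtype=float)
    if drive.shape != (n, n):
        raise ValueError(f"drive pattern must have shape {(n, n)}, got {drive.shape}")
    driven_rows = np.where(np.any(drive != 0, axis=1))[0]
    if driven_rows.size == 0:
        raise ValueError("drive pattern activates no DLPFC row")

    dt = cfg.dt_ms
    n_steps = int(round(cfg.trial_window_ms / dt))
    # one representative neuron per driven row: row members are identical
    dlpfc = IzhikevichPopulation(driven_rows.size, REGULAR_PARAMS, dt=dt)
    dlpfc_drive = drive[driven_rows, 0]
    bg = IzhikevichPopulation(n, REGULAR_PARAMS, dt=dt)

    t_dlpfc: Optional[float] = None
    winner: Optional[int] = None
    t_bg: Optional[float] = None
    row_spikes = np.zeros(n)
    step = 0
    for step in range(1, n_steps + 1):
        fired_rows = dlpfc.step(dlpfc_drive)
        row_spikes[:] = 0.0
        row_spikes[driven_rows[fired_rows]] = 1.0
        if t_dlpfc is None and fired_rows.any():
            t_dlpfc = step * dt
        bg_input = synaptic_input(network.weights, row_spikes)
        bg_fired = bg.step(bg_input)
        if bg_fired.any():
            candidates = [
                (int(j), float(bg.last_crossing_v[j])) for j in np.where(bg_fired)[0]
            ]
            winner = winner_take_all(candidates)
            t_bg = step * dt
            break
    if winner is None or t_bg is None:
        raise NoSpikeError(
            f"no BG spike within the {cfg.trial_window_ms} ms trial window; "
            "check drive current and plastic weights"
        )
    if t_dlpfc is None:  # BG fired on intrinsic dynamics before any volley
        t_dlpfc = t_bg

    # relay the winning channel: BG winner -> thalamus -> PMC (fixed weights).
    # losers are inhibited by the winner-take-all competition and are frozen.
    w_fix = cfg.fixed_edge_weight
    bg_state = NeuronState(v=float(bg.v[winner]), u=float(bg.u[winner]))
    thal_state = NeuronState(v=-65.0, u=REGULAR_PARAMS.b * -65.0)
    pmc_state = NeuronState(v=-65.0, u=REGULAR_PARAMS.b * -65.0)
    bg_drive = float(network.weights[:, winner] @ row_spikes)
    t_pmc: Optional[float] = None
    bg_just_fired = True  # the selection spike itself
    thal_just_fired = False
    for relay_step in range(step + 1, n_steps + 1):
        fired_rows = dlpfc.step(dlpfc_drive)
        row_spikes[:] = 0.0
        row_spikes[driven_rows[fired_rows]] = 1.0
        bg_drive = float(network.weights[:, winner] @ row_spikes)
        thal_in = w_fix if bg_just_fired else 0.0
        pmc_in = w_fix if thal_just_fired else 0.0
        bg_state, bg_just_fired = step_neuron(bg_state, REGULAR_PARAMS, bg_drive, dt)
        thal_state, thal_just_fired = step_neuron(thal_state, REGULAR_PARAMS, thal_in, dt)
        pmc_state, pmc_fired = step_neuron(pmc_state, REGULAR_PARAMS, pmc_in, dt)
        if pmc_fired:
            t_pmc = relay_step * dt
            break

    state_shown = int(driven_rows[0])
    record = TrialRecord(
        state=state_shown,
        intention=int(winner),
        t_dlpfc_ms=float(t_dlpfc),
        t_bg_ms=float(t_bg),
        t_pmc_ms=t_pmc,
        weights_version=network.weights_version,
    )
    return int(winner), record


def route_reward(
    network: BrainNetwork,
    reward: RewardValence,
    record: TrialRecord,
) -> List[PlasticityEvent]:
    """Translate feedback into STDP pairings on the plastic matrix.

    Positive feedback (SNc/VTA gate open): the MOFC pathway fires DLPFC
    before striatum — one LTP event on the rewarded synapse (s, a) — while
    the LOFC pathway, with its (s, a) entry vetoed by MOFC inhibition, fires
    striatum before DLPFC for every other state — LTD on (s', a) for all
    s' ≠ s, reserving intention ``a`` for state ``s``.

    Negative feedback (gate closed, SNc/VTA stimulation zero): only the LOFC
    pathway is active — a single LTD event on (s, a); every other synapse is
    untouched.
    """
    if record is None or record.t_bg_ms is None:
        raise ValueError("route_reward requires a completed trial record with spike times")
    if record.weights_version != network.weights_version:
        raise ValueError(
            "stale trial record: weights changed since this prediction was made"
        )
    cfg = network.config
    s, a = record.state, record.intention
    ltp_dt = -abs(cfg.ltp_lag_ms)
    ltd_dt = +abs(cfg.ltd_lag_ms)
    if reward is RewardValence.POSITIVE:
        events = [PlasticityEvent(s, a, ltp_dt)]
        events.extend(
            PlasticityEvent(s_other, a, ltd_dt)
            for s_other in range(network.n)
            if s_other != s
        )
        return events
    return [PlasticityEvent(s, a, ltd_dt)]
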