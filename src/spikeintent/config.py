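"""Run configuration: every tunable of the model in one flat, YAML-round-trippable record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .izhikevich import DEFAULT_DT_MS
from .stdp import NOMINAL_LAG_MS, STDPParameters


@dataclass(frozen=True)
class RunConfiguration:
    """All tunables of the intention-prediction model.

    Values printed by the source study (neuron reset constants, the two
    striatal (a, b) pairs, the STDP constants) are fixed in their own types;
    everything here is a modelling choice exposed for reproduction runs.
    """

    n_intentions: int = 12
    dt_ms: float = DEFAULT_DT_MS
    trial_window_ms: float = 100.0
    #: constant current driving the active DLPFC category row during a trial
    drive_current: float = 20.0
    #: constant weight of every non-plastic inter-region connection
    fixed_edge_weight: float = 50.0
    #: uniform initial value of the plastic DLPFC→BG weights
    initial_weight: float = 10.0
    #: weight floor, as a fraction of the initial weight
    weight_floor_ratio: float = 1e-3
    #: nominal |Δt| for LTP events (DLPFC leads striatum), ms
    ltp_lag_ms: float = NOMINAL_LAG_MS
    #: nominal |Δt| for LTD events (striatum leads DLPFC), ms
    ltd_lag_ms: float = NOMINAL_LAG_MS
    stdp: STDPParameters = field(default_factory=STDPParameters)
    #: state presentation policy for training: "sequential" or "shuffled"
    presentation_order: str = "sequential"
    seed: int = 0

    @property
    def weight_floor(self) -> float:
        return self.weight_floor_ratio * self.initial_weight

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stdp"] = dataclasses.asdict(self.stdp)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfiguration":
        data = dict(data)
        if "stdp" in data and isinstance(data["stdp"], dict):
            data["stdp"] = STDPParameters(**data["stdp"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfiguration":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace(self, **changes) -> "RunConfiguration":
        return dataclasses.replace(self, **changes)
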