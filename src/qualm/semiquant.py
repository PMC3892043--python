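"""Semi-quantitative stochastic simulation of Boolean models.

External inputs (species without a transition) are assigned a probability of
being active at each step, expressed as a percentage in [0, 100]; internal
species follow the synchronous update of the logical rules. The semi-
quantitative readout is the *activity level*: 100 times the fraction of
active steps within a sliding window of the last ``n`` steps, so a binary
trajectory yields a continuous trace on a 0–100 scale. With every input
percentage in {0, 100} and a window of 1, the simulation degenerates to the
deterministic synchronous trajectory.

Sampling is memoryless (each input is redrawn independently every step) and
driven by a named, seeded generator (NumPy PCG64), so identical seeds give
bit-identical traces. Real-time events — changing an input percentage,
clamping a species (gain-of-function at max level, loss-of-function at 0) or
unclamping it — take effect from their step onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import QualmError
from .dynamics import successor_sync
from .model import LogicalModel, State

__all__ = [
    "Event",
    "SimulationConfig",
    "ActivityTrace",
    "simulate_stochastic",
    "dose_response",
    "apply_event",
    "DoseResponseCurve",
]

RNG_ALGORITHM = "numpy-PCG64"


@dataclass(frozen=True)
class Event:
    """A mid-run intervention applied from step `t` onward."""

    t: int
    kind: str  # set-input-percentage | clamp | unclamp
    species: str
    value: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("set-input-percentage", "clamp", "unclamp"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one stochastic run.

    `input_activities` maps input species to the percentage probability of
    being active at each step. `window` is the sliding-window length for the
    activity level. Species in `clamps` are held at a fixed level.
    """

    steps: int = 800
    window: int = 200
    seed: int = 0
    input_activities: Mapping[str, float] = field(default_factory=dict)
    clamps: Mapping[str, int] = field(default_factory=dict)
    initial_state: Optional[Mapping[str, int]] = None
    events: tuple[Event, ...] = ()

    def validate_for(self, model: LogicalModel) -> None:
        if self.steps <= 0:
            raise QualmError("steps must be positive")
        if not (0 < self.window <= self.steps):
            raise QualmError("window must satisfy 0 < n <= steps")
        for sid, pct in self.input_activities.items():
            if sid not in model.species_by_id:
                raise QualmError(f"unknown species {sid!r} in input activities")
            if sid in model.transition_of:
                raise QualmError(
                    f"species {sid!r} has a transition; activity percentages "
                    "apply to external inputs only"
                )
            if not (0 <= pct <= 100):
                raise QualmError(f"percentage {pct} for {sid!r} outside [0, 100]")
        for sid, level in self.clamps.items():
            sp = model.species_by_id.get(sid)
            if sp is None:
                raise QualmError(f"unknown clamped species {sid!r}")
            if not (0 <= level <= sp.max_level):
                raise QualmError(f"clamp level {level} outside [0, {sp.max_level}]")
        for ev in self.events:
            if ev.species not in model.species_by_id:
                raise QualmError(f"event references unknown species {ev.species!r}")
            if not (0 <= ev.t <= self.steps):
                raise QualmError(
                    f"event at step {ev.t} outside the simulation horizon [0, {self.steps}]"
                )
            if ev.kind == "set-input-percentage":
                if ev.species in model.transition_of:
                    raise QualmError(
                        f"cannot set an input percentage on regulated species {ev.species!r}"
                    )
                if ev.value is None or not (0 <= ev.value <= 100):
                    raise QualmError("set-input-percentage needs a value in [0, 100]")


class ActivityTrace:
    """Binary state series plus windowed activity levels for every species.

    Row 0 holds the initial state; rows 1..T the simulated steps. The
    activity at row t averages the states over the last `window` rows ending
    at t (shorter prefix windows at the start), scaled to 0–100.
    """

    def __init__(
        self,
        species: Sequence[str],
        states: np.ndarray,
        window: int,
        metadata: Optional[dict] = None,
    ):
        self.species = tuple(species)
        self.states = states  # shape (T+1, S), integer levels
        self.window = window
        self.metadata = metadata or {}
        kernel_csum = np.cumsum(states, axis=0, dtype=float)
        padded = np.vstack([np.zeros((1, states.shape[1])), kernel_csum])
        t = np.arange(states.shape[0])
        lo = np.maximum(t - window + 1, 0)
        sums = padded[t + 1] - padded[lo]
        counts = (t - lo + 1).astype(float)[:, None]
        self.activities = 100.0 * sums / counts

    @property
    def steps(self) -> int:
        return self.states.shape[0] - 1

    def state_series(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]

    def activity(self, species: str) -> np.ndarray:
        return self.activities[:, self.species.index(species)]

    def terminal_activity(self, species: str) -> float:
        return float(self.activities[-1, self.species.index(species)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (step, species, state, activity) table."""
        T1, S = self.states.shape
        return pd.DataFrame(
            {
                "step": np.repeat(np.arange(T1), S),
                "species": np.tile(np.array(self.species, dtype=object), T1),
                "state": self.states.ravel(),
                "activity": self.activities.ravel(),
            }
        )


def simulate_stochastic(model: LogicalModel, config: SimulationConfig) -> ActivityTrace:
    """Run one seeded stochastic simulation.

    At each step every unclamped external input is sampled active with its
    configured probability; regulated species take their synchronous target
    computed on the previous state; clamped species hold their level. The
    initial state defaults to all-zero.
    """
    if not model.is_boolean:
        raise QualmError("stochastic simulation requires a Boolean model")
    config.validate_for(model)
    rng = np.random.default_rng(config.seed)
    order = model.species_order
    idx = {s: i for i, s in enumerate(order)}
    inputs = [s for s in model.input_species()]

    percentages = dict(config.input_activities)
    clamps = dict(config.clamps)
    events_at: dict[int, list[Event]] = {}
    for ev in config.events:
        events_at.setdefault(ev.t, []).append(ev)

    state = model.zero_state()
    if config.initial_state is not None:
        state.update(config.initial_state)
    for sid, lvl in clamps.items():
        state[sid] = lvl

    T = config.steps
    out = np.zeros((T + 1, len(order)), dtype=np.int64)
    out[0] = [state[s] for s in order]

    for t in range(1, T + 1):
        for ev in events_at.get(t, ()):
            if ev.kind == "set-input-percentage":
                percentages[ev.species] = float(ev.value)
            elif ev.kind == "clamp":
                sp = model.species_by_id[ev.species]
                level = sp.max_level if ev.value is None else int(ev.value)
                clamps[ev.species] = level
            else:
                clamps.pop(ev.species, None)
        nxt = successor_sync(model, state)
        for sid in inputs:
            if sid in percentages and sid not in clamps:
                nxt[sid] = int(rng.random() < percentages[sid] / 100.0)
            elif sid not in clamps:
                nxt[sid] = state[sid]
        for sid, lvl in clamps.items():
            nxt[sid] = lvl
        state = nxt
        out[t] = [state[s] for s in order]

    meta = {
        "rng": RNG_ALGORITHM,
        "seed": config.seed,
        "steps": T,
        "window": config.window,
    }
    return ActivityTrace(order, out, config.window, metadata=meta)


def apply_event(config: SimulationConfig, event: Event) -> SimulationConfig:
    """Schedule an event on a configuration (trace before `event.t` unchanged)."""
    if event.t > config.steps:
        raise QualmError(
            f"event at step {event.t} beyond the simulation horizon {config.steps}"
        )
    return replace(config, events=config.events + (event,))


@dataclass(frozen=True)
class DoseResponseCurve:
    """Per-simulation records of sampled input percentage and terminal activities."""

    varied_input: str
    tracked: tuple[str, ...]
    records: pd.DataFrame  # columns: sim, pct, species, activity

    def for_species(self, species: str) -> pd.DataFrame:
        return self.records[self.records["species"] == species].reset_index(drop=True)


def dose_response(
    model: LogicalModel,
    varied_input: str,
    tracked: Sequence[str],
    n_sims: int = 100,
    config: Optional[SimulationConfig] = None,
) -> DoseResponseCurve:
    """Input–output dose–response sweep.

    Runs `n_sims` independent simulations (default 100 runs of 800 steps);
    in each, the varied input's percentage is drawn uniformly on [0, 100]
    while other percentages stay fixed, and the terminal activity (mean over
    the last window) of each tracked species is recorded.
    """
    config = config or SimulationConfig()
    if varied_input in model.transition_of:
        raise QualmError(f"{varied_input!r} is regulated; vary an external input")
    if varied_input not in model.species_by_id:
        raise QualmError(f"unknown species {varied_input!r}")
    for sid in tracked:
        if sid not in model.species_by_id:
            raise QualmError(f"unknown tracked species {sid!r}")
    master = np.random.default_rng(config.seed)
    rows = []
    for sim in range(n_sims):
        pct = float(master.uniform(0.0, 100.0))
        run_seed = int(master.integers(0, 2**31 - 1))
        activities = dict(config.input_activities)
        activities[varied_input] = pct
        run_cfg = replace(config, input_activities=activities, seed=run_seed)
        trace = simulate_stochastic(model, run_cfg)
        for sid in tracked:
            rows.append(
                {
                    "sim": sim,
                    "pct": pct,
                    "species": sid,
                    "activity": trace.terminal_activity(sid),
                }
            )
    return DoseResponseCurve(
        varied_input=varied_input,
        tracked=tuple(tracked),
        records=pd.DataFrame(rows, columns=["sim", "pct", "species", "activity"]),
    )
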