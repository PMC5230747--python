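"""Deterministic switch-level simulation of transistor netlists.

The simulator treats each enhancement-mode transistor as a switch that
conducts between its two channel terminals whenever its gate wire is high.
After each stimulus assignment the circuit is relaxed to a fixed point:

1. transistor conduction states are computed from the current wire values
   (respecting lesions),
2. wires are partitioned into *groups* — connected components through the
   channels of conducting transistors,
3. each group is assigned one value by source precedence:
   ground member -> low; else power member -> high; else externally driven
   input member -> the driven value (high wins on conflicting inputs);
   else any depletion-pullup member -> high; else any member that was high
   on the previous pass -> high (charge retention); else low,
4. repeat until no wire changes.

Ground dominating power makes accidental shorts resolve deterministically
(they are logged).  An isolated charged group with no driver retains its
previous value, which is what makes dynamic pass-transistor latches work.
Free-running oscillators are unsupported by construction: circuits that do
not settle raise :class:`UnstableCircuitError` naming the oscillating wires.

Lesions force a single transistor's conduction state: ``stuck_on`` is the
in-silico analogue of tying the device's input high, ``stuck_off`` of
severing it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .netlist import Netlist

__all__ = [
    "CircuitState",
    "StimulusProgram",
    "StateTrace",
    "Lesion",
    "Behavior",
    "LesionScreenResult",
    "UnstableCircuitError",
    "SimulationError",
    "CircuitSimulator",
    "resolve",
    "run",
    "lesion_screen",
]

log = logging.getLogger(__name__)

LESION_MODES = ("stuck_on", "stuck_off")


class SimulationError(Exception):
    pass


class UnstableCircuitError(SimulationError):
    """The circuit failed to settle within the iteration cap."""

    def __init__(self, oscillating_wires: Sequence[int]):
        self.oscillating_wires = tuple(sorted(oscillating_wires))
        super().__init__(
            f"circuit did not settle; oscillating wires: {self.oscillating_wires}"
        )


@dataclass(frozen=True)
class Lesion:
    """Force one transistor permanently conducting or non-conducting."""

    transistor: int
    mode: str = "stuck_on"

    def __post_init__(self):
        if self.mode not in LESION_MODES:
            raise ValueError(f"unknown lesion mode {self.mode!r}")


@dataclass(frozen=True)
class CircuitState:
    """Wire values and transistor conduction states at one settled instant."""

    wire_value: Mapping[int, int]
    transistor_on: Mapping[int, bool]


@dataclass(frozen=True)
class StimulusProgram:
    """Per-timestep drive values for every input wire.

    ``values`` is a (T, n_inputs) array of {0, 1}; column order follows
    ``input_wires``.
    """

    input_wires: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.uint8)
        if vals.ndim != 2 or vals.shape[1] != len(self.input_wires):
            raise ValueError(
                "stimulus values must be (T, n_inputs) matching input_wires"
            )
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("stimulus values must be binary")
        object.__setattr__(self, "values", vals)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_dict(cls, assignments: Mapping[int, Sequence[int]]) -> "StimulusProgram":
        wires = tuple(sorted(assignments))
        cols = [np.asarray(assignments[w], dtype=np.uint8) for w in wires]
        return cls(wires, np.column_stack(cols))

    def validate_against(self, netlist: Netlist) -> None:
        declared = set(netlist.input_ids)
        driven = set(self.input_wires)
        if driven != declared:
            missing = sorted(declared - driven)
            extra = sorted(driven - declared)
            raise SimulationError(
                f"stimulus must drive exactly the input wires; "
                f"missing {missing}, extra/non-input {extra}"
            )

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.input_wires).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]

    def prefix(self, length: int) -> "StimulusProgram":
        return StimulusProgram(self.input_wires, self.values[:length])


@dataclass
class StateTrace:
    """Whole-circuit recording: settled wire and transistor states per step."""

    wire_values: np.ndarray  # (T, n_wires) uint8
    transistor_on: np.ndarray  # (T, n_transistors) uint8
    wire_ids: tuple[int, ...]
    transistor_ids: tuple[int, ...]
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.wire_values.shape[0]

    def wire_trace(self, wire_id: int) -> np.ndarray:
        return self.wire_values[:, self.wire_ids.index(wire_id)]

    def bus_value(self, wire_ids_lsb_first: Sequence[int]) -> np.ndarray:
        """Decode a group of wires as an unsigned integer stream (LSB first)."""
        cols = [self.wire_trace(w).astype(np.int64) for w in wire_ids_lsb_first]
        out = np.zeros(self.length, dtype=np.int64)
        for k, col in enumerate(cols):
            out += col << k
        return out

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("trace")
            g.create_dataset("wire_values", data=self.wire_values, dtype="u1")
            g.create_dataset("transistor_on", data=self.transistor_on, dtype="u1")
            g.create_dataset("wire_ids", data=np.asarray(self.wire_ids))
            g.create_dataset("transistor_ids", data=np.asarray(self.transistor_ids))
            for k, v in self.meta.items():
                g.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "StateTrace":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["trace"]
            return cls(
                wire_values=g["wire_values"][...],
                transistor_on=g["transistor_on"][...],
                wire_ids=tuple(int(i) for i in g["wire_ids"][...]),
                transistor_ids=tuple(int(i) for i in g["transistor_ids"][...]),
                meta=dict(g.attrs),
            )


@dataclass(frozen=True)
class Behavior:
    """A stimulus program plus a success predicate on the resulting trace.

    ``success`` receives the (possibly prefix-truncated) trace and returns
    whether the behavior was produced — the analogue of checking that the
    system still draws the first frame of its game.
    """

    name: str
    stimulus: StimulusProgram
    success: Callable[[StateTrace], bool]
    check_length: int | None = None  # timesteps needed to evaluate success


class CircuitSimulator:
    """Compiled simulation context for one netlist (index arrays cached)."""

    def __init__(self, netlist: Netlist, settle_cap_factor: int = 100):
        netlist.validate()
        self.netlist = netlist
        self.wire_ids = tuple(w.id for w in netlist.wires)
        self.transistor_ids = tuple(t.id for t in netlist.transistors)
        widx = {w: i for i, w in enumerate(self.wire_ids)}
        self._gate = np.array([widx[t.gate] for t in netlist.transistors], dtype=np.intp)
        self._c1 = np.array([widx[t.c1] for t in netlist.transistors], dtype=np.intp)
        self._c2 = np.array([widx[t.c2] for t in netlist.transistors], dtype=np.intp)
        self._pullup = np.array([w.pullup for w in netlist.wires], dtype=bool)
        self._is_power = np.array([w.role == "power" for w in netlist.wires], dtype=bool)
        self._is_ground = np.array([w.role == "ground" for w in netlist.wires], dtype=bool)
        self._is_input = np.array([w.role == "input" for w in netlist.wires], dtype=bool)
        self._input_cols = {
            w: widx[w] for w in netlist.input_ids
        }
        self.n_wires = netlist.n_wires
        self.n_transistors = netlist.n_transistors
        self.settle_cap = settle_cap_factor * max(self.n_wires, 1)
        self._tidx = {t: i for i, t in enumerate(self.transistor_ids)}

    # -- lesion masks -------------------------------------------------------

    def _lesion_masks(self, lesions: Iterable[Lesion]):
        force_on = np.zeros(self.n_transistors, dtype=bool)
        force_off = np.zeros(self.n_transistors, dtype=bool)
        for les in lesions:
            if les.transistor not in self._tidx:
                raise SimulationError(
                    f"lesion references absent transistor {les.transistor}"
                )
            if les.mode == "stuck_on":
                force_on[self._tidx[les.transistor]] = True
            else:
                force_off[self._tidx[les.transistor]] = True
        return force_on, force_off

    def initial_values(self) -> np.ndarray:
        """All non-power wires low — the declared reset baseline."""
        values = np.zeros(self.n_wires, dtype=np.uint8)
        values[self._is_power] = 1
        return values

    def _transistor_on(self, values, force_on, force_off) -> np.ndarray:
        on = values[self._gate].astype(bool)
        on |= force_on
        on &= ~force_off
        return on

    def settle(self, values: np.ndarray, force_on, force_off) -> np.ndarray:
        """Relax wire values to a fixed point (synchronous group passes)."""
        values = values.copy()
        prev = None
        for _ in range(self.settle_cap):
            on = self._transistor_on(values, force_on, force_off)
            n_on = int(on.sum())
            if n_on:
                rows = self._c1[on]
                cols = self._c2[on]
                adj = coo_matrix(
                    (np.ones(n_on, dtype=np.int8), (rows, cols)),
                    shape=(self.n_wires, self.n_wires),
                )
                n_groups, labels = connected_components(adj, directed=False)
            else:
                n_groups = self.n_wires
                labels = np.arange(self.n_wires)
            has_ground = np.bincount(labels, self._is_ground, n_groups) > 0
            has_power = np.bincount(labels, self._is_power, n_groups) > 0
            has_pullup = np.bincount(labels, self._pullup, n_groups) > 0
            prev_high = np.bincount(labels, values.astype(float), n_groups) > 0
            inp_any = np.bincount(labels, self._is_input, n_groups) > 0
            inp_high = (
                np.bincount(labels, (self._is_input & (values == 1)), n_groups) > 0
            )
            if (has_ground & has_power).any():
                log.debug("short circuit: group(s) contain both rails")
            gval = prev_high.astype(np.uint8)
            gval[has_pullup] = 1
            gval[inp_any] = inp_high[inp_any]
            gval[has_power] = 1
            gval[has_ground] = 0
            new = gval[labels]
            # sources keep their own values regardless of group outcome
            new[self._is_power] = 1
            new[self._is_ground] = 0
            new[self._is_input] = values[self._is_input]
            if np.array_equal(new, values):
                return values
            prev, values = values, new
        osc = np.flatnonzero(prev != values) if prev is not None else np.arange(self.n_wires)
        raise UnstableCircuitError([self.wire_ids[i] for i in osc])

    def resolve_state(self, values: np.ndarray,
                      lesions: Iterable[Lesion] = ()) -> tuple[np.ndarray, np.ndarray]:
        force_on, force_off = self._lesion_masks(lesions)
        settled = self.settle(values, force_on, force_off)
        on = self._transistor_on(settled, force_on, force_off)
        return settled, on

    def run(self, stimulus: StimulusProgram,
            lesions: Iterable[Lesion] = (),
            initial: np.ndarray | None = None) -> StateTrace:
        stimulus.validate_against(self.netlist)
        lesions = tuple(lesions)
        force_on, force_off = self._lesion_masks(lesions)
        values = self.initial_values() if initial is None else initial.copy()
        T = stimulus.length
        wire_tr = np.empty((T, self.n_wires), dtype=np.uint8)
        tran_tr = np.empty((T, self.n_transistors), dtype=np.uint8)
        in_cols = [self._input_cols[w] for w in stimulus.input_wires]
        for t in range(T):
            values[in_cols] = stimulus.values[t]
            values = self.settle(values, force_on, force_off)
            wire_tr[t] = values
            tran_tr[t] = self._transistor_on(values, force_on, force_off)
        meta = {
            "stimulus_digest": stimulus.digest(),
            "lesions": repr(sorted((l.transistor, l.mode) for l in lesions)),
        }
        return StateTrace(wire_tr, tran_tr, self.wire_ids, self.transistor_ids, meta)


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def resolve(netlist: Netlist, state: Mapping[int, int] | None = None,
            changed: Iterable[int] = (), lesions: Iterable[Lesion] = ()) -> CircuitState:
    """Settle the circuit from the given wire values to a fixed point.

    ``state`` maps wire id -> {0, 1}; omitted wires start from the all-low
    baseline (power high).  ``changed`` is accepted for callers that track
    dirty wires but does not alter the fixed point.
    """
    sim = CircuitSimulator(netlist)
    values = sim.initial_values()
    if state:
        widx = {w: i for i, w in enumerate(sim.wire_ids)}
        for wid, val in state.items():
            values[widx[wid]] = 1 if val else 0
        values[sim._is_power] = 1
        values[sim._is_ground] = 0
    settled, on = sim.resolve_state(values, lesions)
    return CircuitState(
        wire_value={w: int(v) for w, v in zip(sim.wire_ids, settled)},
        transistor_on={t: bool(o) for t, o in zip(sim.transistor_ids, on)},
    )


def run(netlist: Netlist, stimulus: StimulusProgram,
        lesions: Iterable[Lesion] = ()) -> StateTrace:
    """Simulate a stimulus program; deterministic, bit-identical on reruns."""
    return CircuitSimulator(netlist).run(stimulus, lesions)


@dataclass
class LesionScreenResult:
    """Per-transistor behavioral impact of single-transistor lesions."""

    disrupted: dict[int, frozenset[str]]  # transistor id -> behaviors broken
    behavior_names: tuple[str, ...]
    mode: str

    @property
    def counts(self) -> dict[str, int]:
        n_beh = len(self.behavior_names)
        out = {"disrupts_none": 0, "disrupts_some": 0, "disrupts_all": 0}
        for broken in self.disrupted.values():
            if not broken:
                out["disrupts_none"] += 1
            elif len(broken) == n_beh:
                out["disrupts_all"] += 1
            else:
                out["disrupts_some"] += 1
        return out

    def necessary_for(self, behavior: str) -> frozenset[int]:
        return frozenset(
            t for t, broken in self.disrupted.items() if behavior in broken
        )

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "transistor": t,
                "n_disrupted": len(broken),
                "disrupted": ";".join(sorted(broken)),
            }
            for t, broken in sorted(self.disrupted.items())
        ]
        return pd.DataFrame(rows)


def lesion_screen(netlist: Netlist, behaviors: Sequence[Behavior],
                  mode: str = "stuck_on",
                  transistors: Sequence[int] | None = None) -> LesionScreenResult:
    """Systematically lesion each transistor and record which behaviors break.

    Each behavior's success predicate is evaluated on the simulated trace
    prefix (``Behavior.check_length`` timesteps if set).  A lesioned circuit
    that fails to settle counts as a behavioral failure and is logged.
    """
    if not behaviors:
        raise SimulationError("lesion_screen requires at least one behavior")
    if mode not in LESION_MODES:
        raise SimulationError(f"unknown lesion mode {mode!r}")
    sim = CircuitSimulator(netlist)
    stimuli = []
    for beh in behaviors:
        stim = beh.stimulus
        if beh.check_length is not None:
            stim = stim.prefix(beh.check_length)
        stimuli.append(stim)
        baseline = sim.run(stim)
        if not beh.success(baseline):
            raise SimulationError(
                f"behavior {beh.name!r} fails on the un-lesioned circuit"
            )
    targets = tuple(transistors) if transistors is not None else sim.transistor_ids
    disrupted: dict[int, frozenset[str]] = {}
    for tid in targets:
        broken = set()
        for beh, stim in zip(behaviors, stimuli):
            try:
                trace = sim.run(stim, lesions=[Lesion(tid, mode)])
                ok = beh.success(trace)
            except UnstableCircuitError:
                log.info("lesion %d mode %s: unstable under %s", tid, mode, beh.name)
                ok = False
            if not ok:
                broken.add(beh.name)
        disrupted[tid] = frozenset(broken)
    return LesionScreenResult(
        disrupted=disrupted,
        behavior_names=tuple(b.name for b in behaviors),
        mode=mode,
    )
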