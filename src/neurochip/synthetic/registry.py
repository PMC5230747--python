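"""Ground-truth registries for synthetic fixtures.

A registry is the machine-readable "we know how this system works" record
for one fixture: the netlist with its module annotations, the named control
signals, the behaviors (stimulus programs with their expected scalar output
streams), recording-site coordinates, and any planted surrogate parameters.
Every analysis stage in the battery is scored against a registry.

Expected outputs are produced by an independent clock-level behavioral model
of each fixture, never by the switch-level simulator itself; the registry
self-check verifies at build time that un-lesioned switch-level simulation
reproduces them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..netlist import Netlist, netlist_from_json, netlist_to_json
from ..simulator import Behavior, CircuitSimulator, StateTrace, StimulusProgram

__all__ = ["FixtureBehavior", "GroundTruthRegistry", "SelfCheckError"]


class SelfCheckError(AssertionError):
    """A fixture's simulated output disagrees with its behavioral model."""


@dataclass
class FixtureBehavior:
    """A named stimulus program with its expected scalar output stream."""

    name: str
    stimulus: StimulusProgram
    expected_output: np.ndarray  # one scalar per timestep
    success_prefix: int  # timesteps that must match for "behavior produced"

    def to_behavior(self, output_wires: tuple[int, ...]) -> Behavior:
        expected = np.asarray(self.expected_output)

        def success(trace: StateTrace, _expected=expected,
                    _wires=output_wires, _prefix=self.success_prefix) -> bool:
            got = trace.bus_value(_wires)[:_prefix]
            return bool(np.array_equal(got, _expected[: len(got)]))

        return Behavior(name=self.name, stimulus=self.stimulus,
                        success=success, check_length=self.success_prefix)


@dataclass
class GroundTruthRegistry:
    """Planted truth against which every analysis stage is scored."""

    fixture: str
    netlist: Netlist
    output_wires: tuple[int, ...]  # LSB first; scalar output = bus value
    behaviors: list[FixtureBehavior] = field(default_factory=list)
    lfp_sites: dict[str, tuple[float, float]] = field(default_factory=dict)
    planted: dict = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    @property
    def signals(self) -> dict[str, int]:
        return dict(self.netlist.signals)

    @property
    def modules(self) -> dict[str, frozenset[int]]:
        return dict(self.netlist.modules)

    def behavior(self, name: str) -> FixtureBehavior:
        for beh in self.behaviors:
            if beh.name == name:
                return beh
        raise KeyError(name)

    def behavior_objects(self) -> list[Behavior]:
        return [b.to_behavior(self.output_wires) for b in self.behaviors]

    def signal_trace(self, trace: StateTrace, name: str) -> np.ndarray:
        """The recorded value stream of a named known signal."""
        return trace.wire_trace(self.netlist.signals[name])

    def output_stream(self, trace: StateTrace) -> np.ndarray:
        return trace.bus_value(self.output_wires)

    def module_of(self, transistor_id: int) -> tuple[str, ...]:
        return tuple(
            sorted(label for label, ids in self.netlist.modules.items()
                   if transistor_id in ids)
        )

    # -- consistency --------------------------------------------------------

    def self_check(self) -> None:
        """Simulate every behavior un-lesioned and compare output streams."""
        sim = CircuitSimulator(self.netlist)
        for beh in self.behaviors:
            trace = sim.run(beh.stimulus)
            got = self.output_stream(trace)
            expected = np.asarray(beh.expected_output)
            if not np.array_equal(got, expected[: len(got)]):
                bad = int(np.flatnonzero(got != expected[: len(got)])[0])
                raise SelfCheckError(
                    f"fixture {self.fixture!r}, behavior {beh.name!r}: "
                    f"simulated output diverges from the behavioral model at "
                    f"timestep {bad} (got {got[bad]}, expected {expected[bad]})"
                )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "fixture": self.fixture,
            "output_wires": list(self.output_wires),
            "behaviors": [
                {
                    "name": b.name,
                    "input_wires": list(b.stimulus.input_wires),
                    "stimulus": b.stimulus.values.tolist(),
                    "expected_output": np.asarray(b.expected_output).tolist(),
                    "success_prefix": b.success_prefix,
                }
                for b in self.behaviors
            ],
            "lfp_sites": {k: list(v) for k, v in sorted(self.lfp_sites.items())},
            "planted": self.planted,
        }
        return json.dumps(obj, sort_keys=True, indent=1) + "\n"

    @classmethod
    def from_json(cls, text: str, netlist: Netlist) -> "GroundTruthRegistry":
        obj = json.loads(text)
        behaviors = [
            FixtureBehavior(
                name=b["name"],
                stimulus=StimulusProgram(
                    tuple(b["input_wires"]),
                    np.asarray(b["stimulus"], dtype=np.uint8),
                ),
                expected_output=np.asarray(b["expected_output"]),
                success_prefix=int(b["success_prefix"]),
            )
            for b in obj["behaviors"]
        ]
        return cls(
            fixture=obj["fixture"],
            netlist=netlist,
            output_wires=tuple(obj["output_wires"]),
            behaviors=behaviors,
            lfp_sites={k: (float(v[0]), float(v[1]))
                       for k, v in obj["lfp_sites"].items()},
            planted=obj.get("planted", {}),
        )

    def save(self, directory: str | Path) -> tuple[Path, Path]:
        """Write canonical netlist JSON + registry JSON; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        npath = directory / f"{self.fixture}.netlist.json"
        rpath = directory / f"{self.fixture}.registry.json"
        npath.write_text(netlist_to_json(self.netlist), encoding="utf-8")
        rpath.write_text(self.to_json(), encoding="utf-8")
        return npath, rpath

    @classmethod
    def load(cls, directory: str | Path, fixture: str) -> "GroundTruthRegistry":
        directory = Path(directory)
        netlist = netlist_from_json(
            (directory / f"{fixture}.netlist.json").read_text(encoding="utf-8")
        )
        return cls.from_json(
            (directory / f"{fixture}.registry.json").read_text(encoding="utf-8"),
            netlist,
        )
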