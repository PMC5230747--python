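"""Transistor-level netlists: data model, gate builder, and canonical JSON I/O.

A netlist is the circuit's "connectome": wires, three-terminal enhancement-mode
transistors, named control signals, and ground-truth functional-module labels.
Depletion-mode pullup loads are modelled as a boolean attribute on the wire they
pull high, not as explicit devices — they act purely as static loads.

The JSON serialization is canonical (sorted keys, id-ordered arrays, LF line
endings) so that read/write round-trips are bit-exact and fixture files can be
compared byte-wise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Wire",
    "Transistor",
    "Netlist",
    "Fragment",
    "WireSpace",
    "NetlistError",
    "NetlistParseError",
    "NetlistValidationError",
    "GATE_KINDS",
    "build_gate",
    "compose",
    "read_netlist",
    "write_netlist",
    "netlist_to_json",
    "netlist_from_json",
]

ROLES = ("plain", "power", "ground", "input", "output")


class NetlistError(Exception):
    """Base class for netlist problems."""


class NetlistParseError(NetlistError):
    """Raised when a netlist file violates the JSON schema."""


class NetlistValidationError(NetlistError):
    """Raised when a structurally parsed netlist violates an invariant."""


@dataclass(frozen=True)
class Wire:
    """A circuit node.

    ``pullup`` marks an attached depletion-mode load that pulls the wire high
    whenever nothing conducts it to ground.  ``role`` distinguishes the single
    power and ground rails and externally driven inputs from plain wires.
    """

    id: int
    name: str | None = None
    pullup: bool = False
    role: str = "plain"


@dataclass(frozen=True)
class Transistor:
    """Three-terminal enhancement-mode switch.

    Conducts between channel terminals ``c1`` and ``c2`` whenever the ``gate``
    wire is high.  ``x``/``y`` are abstract layout coordinates in micrometres,
    origin at the lower left.
    """

    id: int
    gate: int
    c1: int
    c2: int
    x: float = 0.0
    y: float = 0.0


@dataclass(frozen=True)
class Netlist:
    """A validated circuit: wires, transistors, signals and module labels."""

    wires: tuple[Wire, ...]
    transistors: tuple[Transistor, ...]
    signals: Mapping[str, int] = field(default_factory=dict)
    modules: Mapping[str, frozenset[int]] = field(default_factory=dict)

    # -- indexing helpers ---------------------------------------------------

    def wire_index(self) -> dict[int, int]:
        return {w.id: i for i, w in enumerate(self.wires)}

    def transistor_index(self) -> dict[int, int]:
        return {t.id: i for i, t in enumerate(self.transistors)}

    @property
    def n_wires(self) -> int:
        return len(self.wires)

    @property
    def n_transistors(self) -> int:
        return len(self.transistors)

    @property
    def power_id(self) -> int:
        return next(w.id for w in self.wires if w.role == "power")

    @property
    def ground_id(self) -> int:
        return next(w.id for w in self.wires if w.role == "ground")

    @property
    def input_ids(self) -> tuple[int, ...]:
        return tuple(w.id for w in self.wires if w.role == "input")

    @property
    def output_ids(self) -> tuple[int, ...]:
        return tuple(w.id for w in self.wires if w.role == "output")

    def wire(self, wire_id: int) -> Wire:
        return self.wires[self.wire_index()[wire_id]]

    def signal_wire(self, name: str) -> int:
        return self.signals[name]

    def positions(self):
        import numpy as np

        return np.array([[t.x, t.y] for t in self.transistors], dtype=float)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "Netlist":
        wire_ids = [w.id for w in self.wires]
        if len(set(wire_ids)) != len(wire_ids):
            dup = sorted({i for i in wire_ids if wire_ids.count(i) > 1})
            raise NetlistValidationError(f"duplicate wire ids: {dup}")
        tran_ids = [t.id for t in self.transistors]
        if len(set(tran_ids)) != len(tran_ids):
            dup = sorted({i for i in tran_ids if tran_ids.count(i) > 1})
            raise NetlistValidationError(f"duplicate transistor ids: {dup}")
        for w in self.wires:
            if w.id < 0:
                raise NetlistValidationError(f"negative wire id {w.id}")
            if w.role not in ROLES:
                raise NetlistValidationError(
                    f"wire {w.id}: unknown role {w.role!r}"
                )
        n_power = sum(w.role == "power" for w in self.wires)
        n_ground = sum(w.role == "ground" for w in self.wires)
        if n_power != 1 or n_ground != 1:
            raise NetlistValidationError(
                f"need exactly one power and one ground wire, "
                f"found {n_power} power / {n_ground} ground"
            )
        for w in self.wires:
            if w.pullup and w.role in ("power", "ground"):
                raise NetlistValidationError(
                    f"wire {w.id}: pullup not allowed on {w.role} rail"
                )
        known = set(wire_ids)
        dangling: list[int] = []
        for t in self.transistors:
            for term in (t.gate, t.c1, t.c2):
                if term not in known:
                    dangling.append(term)
            if t.c1 == t.c2:
                raise NetlistValidationError(
                    f"transistor {t.id}: c1 == c2 == {t.c1}"
                )
            if not (math.isfinite(t.x) and math.isfinite(t.y)):
                raise NetlistValidationError(
                    f"transistor {t.id}: non-finite coordinates"
                )
        if dangling:
            raise NetlistValidationError(
                f"dangling wire references: {sorted(set(dangling))}"
            )
        for name, wid in self.signals.items():
            if wid not in known:
                raise NetlistValidationError(
                    f"signal {name!r} references absent wire {wid}"
                )
        tset = set(tran_ids)
        for label, members in self.modules.items():
            bad = sorted(set(members) - tset)
            if bad:
                raise NetlistValidationError(
                    f"module {label!r} references absent transistors {bad}"
                )
        return self


# ---------------------------------------------------------------------------
# canonical JSON serialization
# ---------------------------------------------------------------------------

def netlist_to_json(nl: Netlist) -> str:
    """Serialize to the canonical form: sorted keys, id-ordered arrays, LF."""
    obj = {
        "wires": [
            {"id": w.id, "name": w.name, "pullup": w.pullup, "role": w.role}
            for w in sorted(nl.wires, key=lambda w: w.id)
        ],
        "transistors": [
            {"id": t.id, "gate": t.gate, "c1": t.c1, "c2": t.c2,
             "x": t.x, "y": t.y}
            for t in sorted(nl.transistors, key=lambda t: t.id)
        ],
        "signals": {k: nl.signals[k] for k in sorted(nl.signals)},
        "modules": {k: sorted(nl.modules[k]) for k in sorted(nl.modules)},
    }
    return json.dumps(obj, sort_keys=True, indent=1, ensure_ascii=False) + "\n"


def _require(obj: Mapping, key: str, typ, where: str):
    if key not in obj:
        raise NetlistParseError(f"{where}: missing field {key!r}")
    val = obj[key]
    if typ is float:
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise NetlistParseError(f"{where}: field {key!r} must be a number")
        return float(val)
    if typ is int:
        if not isinstance(val, int) or isinstance(val, bool):
            raise NetlistParseError(f"{where}: field {key!r} must be an integer")
        return val
    if not isinstance(val, typ):
        raise NetlistParseError(
            f"{where}: field {key!r} has wrong type {type(val).__name__}"
        )
    return val


def netlist_from_json(text: str) -> Netlist:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetlistParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise NetlistParseError("top level must be a JSON object")
    wires = []
    for i, w in enumerate(_require(obj, "wires", list, "netlist")):
        where = f"wires[{i}]"
        if not isinstance(w, dict):
            raise NetlistParseError(f"{where}: must be an object")
        name = w.get("name")
        if name is not None and not isinstance(name, str):
            raise NetlistParseError(f"{where}: field 'name' must be string or null")
        wires.append(
            Wire(
                id=_require(w, "id", int, where),
                name=name,
                pullup=_require(w, "pullup", bool, where),
                role=_require(w, "role", str, where),
            )
        )
    transistors = []
    for i, t in enumerate(_require(obj, "transistors", list, "netlist")):
        where = f"transistors[{i}]"
        if not isinstance(t, dict):
            raise NetlistParseError(f"{where}: must be an object")
        transistors.append(
            Transistor(
                id=_require(t, "id", int, where),
                gate=_require(t, "gate", int, where),
                c1=_require(t, "c1", int, where),
                c2=_require(t, "c2", int, where),
                x=_require(t, "x", float, where),
                y=_require(t, "y", float, where),
            )
        )
    signals_raw = _require(obj, "signals", dict, "netlist")
    signals = {}
    for k, v in signals_raw.items():
        if not isinstance(v, int) or isinstance(v, bool):
            raise NetlistParseError(f"signals[{k!r}]: must be a wire id")
        signals[k] = v
    modules_raw = _require(obj, "modules", dict, "netlist")
    modules = {}
    for k, v in modules_raw.items():
        if not isinstance(v, list) or any(
            not isinstance(i, int) or isinstance(i, bool) for i in v
        ):
            raise NetlistParseError(f"modules[{k!r}]: must be a list of ids")
        modules[k] = frozenset(v)
    nl = Netlist(
        wires=tuple(sorted(wires, key=lambda w: w.id)),
        transistors=tuple(sorted(transistors, key=lambda t: t.id)),
        signals=signals,
        modules=modules,
    )
    return nl.validate()


def read_netlist(path: str | Path) -> Netlist:
    """Read and validate a netlist from a canonical-schema JSON file."""
    return netlist_from_json(Path(path).read_text(encoding="utf-8"))


def write_netlist(nl: Netlist, path: str | Path) -> None:
    """Write a netlist in canonical JSON form (bit-exact round-trips)."""
    Path(path).write_text(netlist_to_json(nl), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# builder DSL: shared wire namespace + gate fragments
# ---------------------------------------------------------------------------

GATE_KINDS = ("not", "nand2", "nor2", "pass_latch", "dff_2phase")


class WireSpace:
    """Shared wire namespace used when composing gate fragments.

    All fragments of one circuit allocate wires from the same space so that
    gates can reference each other's nodes by id.
    """

    def __init__(self):
        self._wires: dict[int, Wire] = {}
        self._next = 0
        self.power = self.add(name="VCC", role="power")
        self.ground = self.add(name="GND", role="ground")

    def add(self, name: str | None = None, pullup: bool = False,
            role: str = "plain") -> int:
        wid = self._next
        self._next += 1
        self._wires[wid] = Wire(id=wid, name=name, pullup=pullup, role=role)
        return wid

    def input(self, name: str) -> int:
        return self.add(name=name, role="input")

    def output(self, name: str) -> int:
        return self.add(name=name, role="output")

    def set_pullup(self, wire_id: int, pullup: bool = True) -> None:
        w = self._wires[wire_id]
        if w.role in ("power", "ground"):
            raise NetlistError(f"cannot attach pullup to {w.role} rail {wire_id}")
        self._wires[wire_id] = replace(w, pullup=pullup)

    def wire(self, wire_id: int) -> Wire:
        return self._wires[wire_id]

    def __contains__(self, wire_id: int) -> bool:
        return wire_id in self._wires

    def wires(self) -> tuple[Wire, ...]:
        return tuple(self._wires[k] for k in sorted(self._wires))


@dataclass
class Fragment:
    """A set of transistors over a shared :class:`WireSpace`.

    Transistor ids are provisional; :func:`compose` renumbers them.
    """

    space: WireSpace
    transistors: list[Transistor] = field(default_factory=list)

    def add_transistor(self, gate: int, c1: int, c2: int,
                       x: float = 0.0, y: float = 0.0) -> Transistor:
        for term in (gate, c1, c2):
            if term not in self.space:
                raise NetlistError(f"transistor references unknown wire {term}")
        t = Transistor(id=len(self.transistors), gate=gate, c1=c1, c2=c2,
                       x=float(x), y=float(y))
        self.transistors.append(t)
        return t

    def extend(self, other: "Fragment") -> None:
        if other.space is not self.space:
            raise NetlistError("fragments do not share a wire namespace")
        for t in other.transistors:
            self.add_transistor(t.gate, t.c1, t.c2, t.x, t.y)


def build_gate(space: WireSpace, kind: str, inputs: Sequence[int],
               output: int, at: tuple[float, float] = (0.0, 0.0),
               pitch: float = 10.0) -> Fragment:
    """Append an NMOS pullup/pulldown-style gate as a new fragment.

    Static gates (``not``, ``nand2``, ``nor2``) drive ``output`` through a
    depletion pullup plus an enhancement pulldown network.  ``pass_latch``
    stores its input on a dynamic node behind a pass transistor (gated by its
    clock input) and presents the inverted stored value, statically driven, on
    ``output``; ``dff_2phase`` chains two such stages on opposite clock phases,
    so ``output`` follows the data input with one full clock of delay.
    """
    if kind not in GATE_KINDS:
        raise NetlistError(f"unknown gate kind {kind!r}")
    for wid in list(inputs) + [output]:
        if wid not in space:
            raise NetlistError(f"gate references unknown wire {wid}")
    if space.wire(output).role in ("power", "ground"):
        raise NetlistError(f"cannot drive {space.wire(output).role} rail {output}")
    x0, y0 = at
    frag = Fragment(space)

    def expect(n: int):
        if len(inputs) != n:
            raise NetlistError(f"{kind} expects {n} inputs, got {len(inputs)}")

    if kind == "not":
        expect(1)
        space.set_pullup(output)
        frag.add_transistor(inputs[0], output, space.ground, x0, y0)
    elif kind == "nand2":
        expect(2)
        space.set_pullup(output)
        mid = space.add(name=None)
        frag.add_transistor(inputs[0], output, mid, x0, y0)
        frag.add_transistor(inputs[1], mid, space.ground, x0 + pitch, y0)
    elif kind == "nor2":
        expect(2)
        space.set_pullup(output)
        frag.add_transistor(inputs[0], output, space.ground, x0, y0)
        frag.add_transistor(inputs[1], output, space.ground, x0 + pitch, y0)
    elif kind == "pass_latch":
        expect(2)  # (data, clock)
        data, clock = inputs
        store = space.add(name=None)  # dynamic node: retains charge
        space.set_pullup(output)
        frag.add_transistor(clock, data, store, x0, y0)
        frag.add_transistor(store, output, space.ground, x0 + pitch, y0)
    elif kind == "dff_2phase":
        expect(3)  # (data, clk_phase0, clk_phase1)
        data, clk0, clk1 = inputs
        n1 = space.add(name=None)
        frag.extend(build_gate(space, "pass_latch", (data, clk0), n1,
                               at=(x0, y0), pitch=pitch))
        frag.extend(build_gate(space, "pass_latch", (n1, clk1), output,
                               at=(x0 + 2 * pitch, y0), pitch=pitch))
    return frag


def compose(*fragments: Fragment,
            signals: Mapping[str, int] | None = None,
            modules: Mapping[str, Iterable[Transistor]] | None = None,
            space: WireSpace | None = None) -> Netlist:
    """Merge fragments sharing one wire namespace into a validated netlist.

    Transistors are renumbered 0..n-1 in fragment order.  ``modules`` maps a
    label to the transistor objects that belong to it (typically a fragment's
    ``transistors`` list); the renumbering is applied to them as well.
    """
    if fragments:
        space = fragments[0].space
    if space is None:
        raise NetlistError("compose of zero fragments requires a wire space")
    renumber: dict[int, int] = {}
    transistors: list[Transistor] = []
    for frag in fragments:
        if frag.space is not space:
            raise NetlistError("fragments do not share a wire namespace")
        for t in frag.transistors:
            key = id(t)
            if key in renumber:
                raise NetlistError(
                    f"transistor id collision: fragment transistor {t.id} "
                    "appears in more than one fragment"
                )
            renumber[key] = len(transistors)
            transistors.append(replace(t, id=len(transistors)))
    module_map: dict[str, frozenset[int]] = {}
    if modules:
        for label, members in modules.items():
            ids = []
            for t in members:
                if id(t) not in renumber:
                    raise NetlistError(
                        f"module {label!r} references a transistor outside "
                        "the composed fragments"
                    )
                ids.append(renumber[id(t)])
            module_map[label] = frozenset(ids)
    nl = Netlist(
        wires=space.wires(),
        transistors=tuple(transistors),
        signals=dict(signals or {}),
        modules=module_map,
    )
    return nl.validate()
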