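"""Independent brute-force oracles and random-circuit generators.

The settling oracle reimplements the declared switch-level semantics from
scratch in plain Python (dict/BFS, full synchronous relaxation each pass),
sharing no code with the package's vectorized simulator.  It exists so the
simulator can be checked against an independent derivation of the same
fixed-point semantics on randomly generated circuits.
"""

from __future__ import annotations

import numpy as np

from neurochip.netlist import Netlist, Transistor, Wire


class OracleUnstable(Exception):
    pass


def relax_settle(netlist: Netlist, input_values: dict[int, int],
                 lesions: dict[int, str] | None = None,
                 init: dict[int, int] | None = None):
    """Full synchronous relaxation to a fixed point; returns (values, on).

    Group precedence per pass: ground member -> 0; power member -> 1; driven
    input member -> 1 if any input member is driven high else 0; pullup
    member -> 1; any member high on the previous pass -> 1; else 0.
    """
    lesions = lesions or {}
    wires = {w.id: w for w in netlist.wires}
    power = netlist.power_id
    ground = netlist.ground_id
    values = {wid: 0 for wid in wires}
    values[power] = 1
    if init:
        values.update(init)
    for wid, val in input_values.items():
        values[wid] = val
    cap = 100 * len(wires)
    for _ in range(cap):
        on = {}
        for t in netlist.transistors:
            if t.id in lesions:
                on[t.id] = lesions[t.id] == "stuck_on"
            else:
                on[t.id] = values[t.gate] == 1
        adj = {wid: [] for wid in wires}
        for t in netlist.transistors:
            if on[t.id]:
                adj[t.c1].append(t.c2)
                adj[t.c2].append(t.c1)
        new = {}
        seen = set()
        for start in wires:
            if start in seen:
                continue
            group = [start]
            seen.add(start)
            stack = [start]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        group.append(v)
                        stack.append(v)
            if ground in group:
                val = 0
            elif power in group:
                val = 1
            else:
                inputs = [g for g in group if wires[g].role == "input"]
                if inputs:
                    val = 1 if any(values[g] == 1 for g in inputs) else 0
                elif any(wires[g].pullup for g in group):
                    val = 1
                elif any(values[g] == 1 for g in group):
                    val = 1
                else:
                    val = 0
            for g in group:
                new[g] = val
        new[power] = 1
        new[ground] = 0
        for wid, val in input_values.items():
            new[wid] = val
        if new == values:
            return values, on
        values = new
    raise OracleUnstable("oracle did not settle")


def random_netlist(rng: np.random.Generator, n_transistors: int = 12,
                   n_plain: int | None = None, n_inputs: int = 2) -> Netlist:
    """A random small circuit: arbitrary terminal wiring, some pullups."""
    if n_plain is None:
        n_plain = int(rng.integers(4, 9))
    wires = [Wire(0, "VCC", False, "power"), Wire(1, "GND", False, "ground")]
    next_id = 2
    for k in range(n_inputs):
        wires.append(Wire(next_id, f"IN{k}", False, "input"))
        next_id += 1
    for k in range(n_plain):
        wires.append(Wire(next_id, None, bool(rng.random() < 0.5), "plain"))
        next_id += 1
    wire_ids = [w.id for w in wires]
    transistors = []
    for tid in range(n_transistors):
        gate = int(rng.choice(wire_ids))
        c1, c2 = rng.choice(wire_ids, size=2, replace=False)
        transistors.append(
            Transistor(tid, gate, int(c1), int(c2),
                       x=float(rng.integers(0, 100)),
                       y=float(rng.integers(0, 100)))
        )
    return Netlist(wires=tuple(wires), transistors=tuple(transistors)).validate()


def random_input_assignment(rng: np.random.Generator, netlist: Netlist) -> dict[int, int]:
    return {wid: int(rng.integers(0, 2)) for wid in netlist.input_ids}
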