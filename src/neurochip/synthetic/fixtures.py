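"""Synthetic ground-truth circuit fixtures.

These small two-phase-clocked NMOS circuits stand in for a full processor:
every fixture ships with annotated functional modules, named control
signals, spatially separated layout regions (so field-potential and
component-map analyses are meaningful), and behaviors whose expected output
streams come from an independent clock-level behavioral model.

Fixtures:

``adder4``
    Combinational 4-bit ripple-carry adder built from NAND-gate full adders;
    scalar output is the 5-bit sum, so the exhaustive behavior's expected
    stream is simply a + b.
``shiftreg8``
    8-stage dynamic shift register (two-phase pass-transistor latches).
``counter3_decoder``
    Free-running 3-bit synchronous counter plus a one-hot 3-to-8 decoder;
    the counter bits toggle with periods 2, 4 and 8 clock cycles, giving
    region-specific periodicities for spectral analyses.
``microfsm``
    A ~200-transistor accumulator machine: program counter, instruction
    decoder, ripple adder, accumulator, and an output register.  The
    counter's top bit acts as a read/write-style control line, toggling the
    machine between a fetch phase (accumulate the input bus) and a write
    phase (latch the accumulator onto the output bus).

Clocking convention: one clock cycle is two timesteps — phase 0 (CLK0 high)
samples into the first latch stage, phase 1 (CLK1 high) transfers to the
outputs, so registers visibly change on phase-1 timesteps.  From the all-low
initial state every dynamic latch reads back high, so registers start at
all-ones; the behavioral models start from the same state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..netlist import Fragment, Netlist, WireSpace, build_gate, compose
from ..simulator import StimulusProgram
from .registry import FixtureBehavior, GroundTruthRegistry

__all__ = ["make_fixture", "FIXTURE_NAMES", "CLOCK_STEPS_PER_CYCLE"]

FIXTURE_NAMES = ("adder4", "shiftreg8", "counter3_decoder", "microfsm")
CLOCK_STEPS_PER_CYCLE = 2


# ---------------------------------------------------------------------------
# structural helper: gate-level circuit with modules and layout regions
# ---------------------------------------------------------------------------

@dataclass
class _Region:
    center: tuple[float, float]
    pitch: float = 30.0
    per_row: int = 8
    count: int = 0

    def next_at(self) -> tuple[float, float]:
        row, col = divmod(self.count, self.per_row)
        self.count += 1
        x0 = self.center[0] - self.per_row * self.pitch / 2
        y0 = self.center[1]
        return (x0 + col * self.pitch, y0 + row * self.pitch)


class _Circuit:
    """Gate-level construction buffer over a shared wire namespace."""

    def __init__(self):
        self.space = WireSpace()
        self.fragments: list[Fragment] = []
        self.modules: dict[str, list] = {}
        self.regions: dict[str, _Region] = {}

    def region(self, module: str, center: tuple[float, float]) -> None:
        self.regions[module] = _Region(center=center)

    def _place(self, module: str) -> tuple[float, float]:
        return self.regions[module].next_at()

    def gate(self, kind: str, inputs, output: int, module: str) -> int:
        frag = build_gate(self.space, kind, inputs, output,
                          at=self._place(module))
        self.fragments.append(frag)
        self.modules.setdefault(module, []).extend(frag.transistors)
        return output

    # gate-level vocabulary -------------------------------------------------

    def wire(self, name: str | None = None) -> int:
        return self.space.add(name=name)

    def not_(self, a: int, module: str, out: int | None = None) -> int:
        out = self.wire() if out is None else out
        return self.gate("not", (a,), out, module)

    def nand2(self, a: int, b: int, module: str, out: int | None = None) -> int:
        out = self.wire() if out is None else out
        return self.gate("nand2", (a, b), out, module)

    def and2(self, a: int, b: int, module: str, out: int | None = None) -> int:
        n = self.nand2(a, b, module)
        return self.not_(n, module, out=out)

    def and3(self, a: int, b: int, c: int, module: str,
             out: int | None = None) -> int:
        ab = self.and2(a, b, module)
        return self.and2(ab, c, module, out=out)

    def xor2(self, a: int, b: int, module: str, out: int | None = None) -> int:
        n = self.nand2(a, b, module)
        n2 = self.nand2(a, n, module)
        n3 = self.nand2(b, n, module)
        out = self.wire() if out is None else out
        return self.nand2(n2, n3, module, out=out)

    def dff(self, d: int, clk0: int, clk1: int, module: str,
            out: int | None = None) -> int:
        out = self.wire() if out is None else out
        return self.gate("dff_2phase", (d, clk0, clk1), out, module)

    def pass_t(self, gate_wire: int, a: int, b: int, module: str) -> None:
        """A single pass transistor conducting between a and b."""
        frag = Fragment(self.space)
        x, y = self._place(module)
        frag.add_transistor(gate_wire, a, b, x, y)
        self.fragments.append(frag)
        self.modules.setdefault(module, []).extend(frag.transistors)

    def gated_dff(self, d: int, clk0: int, enable: int, clk1: int,
                  module: str, out: int | None = None) -> int:
        """Two-phase register sampling only when ``enable`` is high.

        The sample path is two series pass transistors: data - enable gate -
        mid - clock gate - sample node.  Gating with the raw phase-0 clock
        next to the sample node isolates it the instant the clock phase
        drops; a derived (ANDed) clock wire would decay a couple of
        relaxation passes later and could sample the transfer-phase
        transient.  The enable transistor sits on the data side so the mid
        node always carries either the live data value or the held sample,
        never a stale charge that could back-drive the sample node.  The
        transfer stage runs every cycle, so a disabled register simply
        re-transfers its held sample.
        """
        out = self.wire() if out is None else out
        mid = self.wire()
        s1 = self.wire()
        self.pass_t(enable, d, mid, module)
        self.pass_t(clk0, mid, s1, module)
        n1 = self.not_(s1, module)
        return self.gate("pass_latch", (n1, clk1), out, module)

    def full_adder(self, a: int, b: int, cin: int, module: str,
                   s_out: int | None = None) -> tuple[int, int]:
        """Classic 9-NAND full adder; returns (sum, carry-out) wires."""
        n1 = self.nand2(a, b, module)
        n2 = self.nand2(a, n1, module)
        n3 = self.nand2(b, n1, module)
        x = self.nand2(n2, n3, module)  # a xor b
        n5 = self.nand2(x, cin, module)
        n6 = self.nand2(x, n5, module)
        n7 = self.nand2(cin, n5, module)
        s = self.nand2(n6, n7, module, out=s_out)
        cout = self.nand2(n5, n1, module)
        return s, cout

    def ripple_adder(self, a_bits, b_bits, cin: int, module: str,
                     sum_wires=None) -> tuple[list[int], int]:
        sums = []
        carry = cin
        for k, (a, b) in enumerate(zip(a_bits, b_bits)):
            s_out = None if sum_wires is None else sum_wires[k]
            s, carry = self.full_adder(a, b, carry, module, s_out=s_out)
            sums.append(s)
        return sums, carry

    def build(self, signals: dict[str, int]) -> Netlist:
        return compose(*self.fragments, signals=signals,
                       modules={k: v for k, v in self.modules.items()})


RESET_STEPS = 2  # leading timesteps with both clock phases held low


def _two_phase_clock(n_cycles: int) -> tuple[np.ndarray, np.ndarray]:
    """Alternating non-overlapping phases, preceded by the reset prefix."""
    clk0 = np.concatenate(
        [np.zeros(RESET_STEPS, dtype=np.uint8), np.tile([1, 0], n_cycles)]
    ).astype(np.uint8)
    clk1 = np.concatenate(
        [np.zeros(RESET_STEPS, dtype=np.uint8), np.tile([0, 1], n_cycles)]
    ).astype(np.uint8)
    return clk0, clk1


def _per_cycle_to_steps(values_per_cycle: np.ndarray) -> np.ndarray:
    """Hold each per-cycle value over both timesteps of its cycle, after
    repeating the first value over the reset prefix."""
    arr = np.asarray(values_per_cycle)
    stepped = np.repeat(arr, CLOCK_STEPS_PER_CYCLE, axis=0)
    prefix = np.repeat(arr[:1], RESET_STEPS, axis=0)
    return np.concatenate([prefix, stepped], axis=0)


def _register_stream(per_cycle_state: np.ndarray) -> np.ndarray:
    """Timestep-resolution stream of a register updating on phase-1 steps.

    ``per_cycle_state[c]`` is the register value during the phase-0 step of
    cycle c; the phase-1 step already shows the next cycle's value.  The
    reset-prefix steps show the initial value.
    """
    q = np.asarray(per_cycle_state)
    out = np.empty(RESET_STEPS + 2 * (len(q) - 1), dtype=q.dtype)
    out[:RESET_STEPS] = q[0]
    out[RESET_STEPS::2] = q[:-1]
    out[RESET_STEPS + 1::2] = q[1:]
    return out


# ---------------------------------------------------------------------------
# adder4
# ---------------------------------------------------------------------------

def _make_adder4(seed: int) -> GroundTruthRegistry:
    c = _Circuit()
    c.region("adder", (0.0, 0.0))
    a_bits = [c.space.input(f"A{k}") for k in range(4)]
    b_bits = [c.space.input(f"B{k}") for k in range(4)]
    zero = c.space.add(name="CZERO")  # undriven, stays low: carry-in of 0
    sum_wires = [c.space.output(f"S{k}") for k in range(4)]
    sums, cout = c.ripple_adder(a_bits, b_bits, zero, "adder",
                                sum_wires=sum_wires)
    # expose the carry as a fifth output bit so the scalar output is a + b
    carry_out = c.space.output("COUT")
    c.not_(c.not_(cout, "adder"), "adder", out=carry_out)
    signals = {f"A{k}": a_bits[k] for k in range(4)}
    signals |= {f"B{k}": b_bits[k] for k in range(4)}
    signals |= {f"S{k}": sum_wires[k] for k in range(4)}
    signals["COUT"] = carry_out
    netlist = c.build(signals)

    rng = np.random.default_rng(seed)
    input_wires = tuple(a_bits + b_bits)

    def behavior_from_pairs(name: str, pairs: np.ndarray) -> FixtureBehavior:
        bits = np.zeros((len(pairs), 8), dtype=np.uint8)
        for k in range(4):
            bits[:, k] = (pairs[:, 0] >> k) & 1
            bits[:, 4 + k] = (pairs[:, 1] >> k) & 1
        stim = StimulusProgram(input_wires, bits)
        expected = pairs[:, 0] + pairs[:, 1]  # behavioral model of an adder
        return FixtureBehavior(name=name, stimulus=stim,
                               expected_output=expected,
                               success_prefix=len(pairs))

    all_pairs = np.array([(a, b) for a in range(16) for b in range(16)])
    behaviors = [behavior_from_pairs("exhaustive", all_pairs)]
    for name in ("sample_a", "sample_b"):
        idx = rng.choice(256, size=48, replace=False)
        behaviors.append(behavior_from_pairs(name, all_pairs[idx]))
    reg = GroundTruthRegistry(
        fixture="adder4",
        netlist=netlist,
        output_wires=tuple(sum_wires) + (carry_out,),
        behaviors=behaviors,
        lfp_sites={"adder": (0.0, 0.0)},
    )
    reg.self_check()
    return reg


# ---------------------------------------------------------------------------
# shiftreg8
# ---------------------------------------------------------------------------

def _make_shiftreg(seed: int, n_stages: int = 8) -> GroundTruthRegistry:
    c = _Circuit()
    for k in range(n_stages):
        c.region(f"stage{k}", (k * 2000.0, 0.0))
    clk0 = c.space.input("CLK0")
    clk1 = c.space.input("CLK1")
    sin = c.space.input("SIN")
    stages = []
    d = sin
    for k in range(n_stages):
        out = (c.space.output(f"Q{k}") if k == n_stages - 1
               else c.space.add(name=f"Q{k}"))
        c.dff(d, clk0, clk1, f"stage{k}", out=out)
        stages.append(out)
        d = out
    signals = {"CLK0": clk0, "CLK1": clk1, "SIN": sin}
    signals |= {f"Q{k}": stages[k] for k in range(n_stages)}
    netlist = c.build(signals)

    rng = np.random.default_rng(seed)
    n_cycles = 64
    c0, c1 = _two_phase_clock(n_cycles)

    def behavior(name: str, pattern: np.ndarray) -> FixtureBehavior:
        sin_per_cycle = np.zeros(n_cycles, dtype=np.uint8)
        sin_per_cycle[: len(pattern)] = pattern
        stim = StimulusProgram(
            (clk0, clk1, sin),
            np.column_stack([c0, c1, _per_cycle_to_steps(sin_per_cycle)]),
        )
        # behavioral model: all stages start high; one-stage delay per cycle
        q = np.ones((n_cycles + 1, n_stages), dtype=np.uint8)
        for cyc in range(n_cycles):
            q[cyc + 1, 0] = sin_per_cycle[cyc]
            q[cyc + 1, 1:] = q[cyc, :-1]
        expected = _register_stream(q[:, -1])
        return FixtureBehavior(name=name, stimulus=stim,
                               expected_output=expected,
                               success_prefix=RESET_STEPS + 2 * n_cycles)

    behaviors = [
        behavior("pattern_1011", np.array([1, 0, 1, 1], dtype=np.uint8)),
        behavior("random_a", rng.integers(0, 2, n_cycles).astype(np.uint8)),
        behavior("random_b", rng.integers(0, 2, n_cycles).astype(np.uint8)),
    ]
    reg = GroundTruthRegistry(
        fixture="shiftreg8",
        netlist=netlist,
        output_wires=(stages[-1],),
        behaviors=behaviors,
        lfp_sites={f"stage{k}": (k * 2000.0, 0.0) for k in range(n_stages)},
    )
    reg.self_check()
    return reg


# ---------------------------------------------------------------------------
# counter3_decoder
# ---------------------------------------------------------------------------

def _build_counter3(c: _Circuit, clk0: int, clk1: int,
                    module_prefix: str = "counter") -> list[int]:
    """3-bit synchronous binary up-counter; returns [q0, q1, q2]."""
    q = [c.space.add(name=f"{module_prefix.upper()}{k}") for k in range(3)]
    logic = f"{module_prefix}_logic"
    d0 = c.not_(q[0], logic)
    d1 = c.xor2(q[0], q[1], logic)
    t01 = c.and2(q[0], q[1], logic)
    d2 = c.xor2(q[2], t01, logic)
    for k, d in enumerate((d0, d1, d2)):
        c.dff(d, clk0, clk1, f"{module_prefix}_bit{k}", out=q[k])
    return q


def _build_decoder8(c: _Circuit, bits: list[int], module: str) -> list[int]:
    """One-hot 3-to-8 decoder over ``bits`` (LSB first)."""
    nbits = [c.not_(b, module) for b in bits]
    lines = []
    for j in range(8):
        sel = [bits[k] if (j >> k) & 1 else nbits[k] for k in range(3)]
        # low bits first, MSB last: the final AND stage is gated by q2/!q2
        out = c.space.add(name=f"DEC{j}")
        c.and2(c.and2(sel[0], sel[1], module), sel[2], module, out=out)
        lines.append(out)
    return lines


def _counter_state_stream(n_cycles: int, start: int = 7) -> np.ndarray:
    per_cycle = (start + np.arange(n_cycles + 1)) % 8
    return per_cycle


def _make_counter3_decoder(seed: int) -> GroundTruthRegistry:
    c = _Circuit()
    c.region("counter_bit0", (0.0, 0.0))
    c.region("counter_bit1", (5000.0, 0.0))
    c.region("counter_bit2", (10000.0, 0.0))
    c.region("counter_logic", (5000.0, 5000.0))
    c.region("decoder", (15000.0, 0.0))
    clk0 = c.space.input("CLK0")
    clk1 = c.space.input("CLK1")
    q = _build_counter3(c, clk0, clk1)
    dec = _build_decoder8(c, q, "decoder")
    signals = {"CLK0": clk0, "CLK1": clk1}
    signals |= {f"Q{k}": q[k] for k in range(3)}
    signals |= {f"DEC{j}": dec[j] for j in range(8)}
    netlist = c.build(signals)

    n_cycles = 512
    c0, c1 = _two_phase_clock(n_cycles)
    stim = StimulusProgram((clk0, clk1), np.column_stack([c0, c1]))
    expected = _register_stream(_counter_state_stream(n_cycles))
    behaviors = [
        FixtureBehavior(name="freerun", stimulus=stim,
                        expected_output=expected,
                        success_prefix=RESET_STEPS + 2 * n_cycles)
    ]
    reg = GroundTruthRegistry(
        fixture="counter3_decoder",
        netlist=netlist,
        output_wires=tuple(q),
        behaviors=behaviors,
        lfp_sites={
            "counter_bit0": (0.0, 0.0),
            "counter_bit1": (5000.0, 0.0),
            "counter_bit2": (10000.0, 0.0),
            "decoder": (15000.0, 0.0),
        },
        planted={
            # conduction-state period of each counter bit, in timesteps
            "bit_state_periods": {"Q0": 4, "Q1": 8, "Q2": 16},
            # spike (rising-edge) period of each counter bit, in timesteps
            "bit_spike_periods": {"Q0": 4, "Q1": 8, "Q2": 16},
        },
    )
    reg.self_check()
    return reg


# ---------------------------------------------------------------------------
# microfsm
# ---------------------------------------------------------------------------

def _microfsm_model(in_per_cycle: np.ndarray):
    """Clock-level behavioral model of the accumulator machine.

    Per cycle c: the program counter increments; during fetch cycles
    (pc bit 2 low) the accumulator's sample stage latches acc + input mod 16;
    during write cycles (pc bit 2 high) the output register's sample stage
    latches the accumulator.  A register's visible value is its sample-stage
    content from the previous cycle (the second latch transfers every
    cycle), so gated registers emerge from reset reading all-ones but fall
    back to their sample node's initial low state after the first transfer.
    Returns per-cycle arrays (pc, acc, out) of length n_cycles + 1.
    """
    n_cycles = len(in_per_cycle)
    pc = np.empty(n_cycles + 1, dtype=np.int64)
    acc = np.empty(n_cycles + 1, dtype=np.int64)
    out = np.empty(n_cycles + 1, dtype=np.int64)
    pc[0], acc[0], out[0] = 7, 15, 15  # all register bits read high at reset
    s1_acc = 0  # sample-stage nodes start low
    s1_out = 0
    for cyc in range(n_cycles):
        write = (pc[cyc] >> 2) & 1
        if write:
            s1_out = acc[cyc]
        else:
            s1_acc = (acc[cyc] + in_per_cycle[cyc]) % 16
        pc[cyc + 1] = (pc[cyc] + 1) % 8
        acc[cyc + 1] = s1_acc
        out[cyc + 1] = s1_out
    return pc, acc, out


def _make_microfsm(seed: int, n_cycles: int = 1024) -> GroundTruthRegistry:
    c = _Circuit()
    c.region("program_counter", (0.0, 0.0))
    c.region("counter_logic", (0.0, 3000.0))
    c.region("decoder", (6000.0, 0.0))
    c.region("control", (12000.0, 0.0))
    c.region("adder", (0.0, 6000.0))
    c.region("accumulator", (6000.0, 6000.0))
    c.region("output_register", (12000.0, 6000.0))

    clk0 = c.space.input("CLK0")
    clk1 = c.space.input("CLK1")
    in_bits = [c.space.input(f"IN{k}") for k in range(4)]

    # program counter: 3-bit free-running cycle counter
    pc = [c.space.add(name=f"PC{k}") for k in range(3)]
    d0 = c.not_(pc[0], "counter_logic")
    d1 = c.xor2(pc[0], pc[1], "counter_logic")
    t01 = c.and2(pc[0], pc[1], "counter_logic")
    d2 = c.xor2(pc[2], t01, "counter_logic")
    for k, d in enumerate((d0, d1, d2)):
        c.dff(d, clk0, clk1, "program_counter", out=pc[k])

    # instruction decoder: one-hot machine-state lines
    dec = _build_decoder8(c, pc, "decoder")

    # control: read/write-analogue line (and its complement) from pc bit 2
    nrw = c.space.add(name="NRW")
    c.not_(pc[2], "control", out=nrw)
    rw = c.space.add(name="RW")
    c.not_(nrw, "control", out=rw)
    # a couple of extra consumers keep the control lines realistically loaded
    c.not_(rw, "control")
    c.not_(nrw, "control")

    # datapath: accumulator + input bus -> ripple adder -> accumulator;
    # the accumulator samples only during fetch cycles (NRW high)
    acc = [c.space.add(name=f"ACC{k}") for k in range(4)]
    sums, _cout = c.ripple_adder(acc, in_bits, c.space.add(name="CZERO"),
                                 "adder")
    for k in range(4):
        c.gated_dff(sums[k], clk0, nrw, clk1, "accumulator", out=acc[k])

    # output register: latches the accumulator during write cycles (RW high)
    out_bits = [c.space.output(f"OUT{k}") for k in range(4)]
    for k in range(4):
        c.gated_dff(acc[k], clk0, rw, clk1, "output_register",
                    out=out_bits[k])

    signals = {"CLK0": clk0, "CLK1": clk1, "RW": rw, "NRW": nrw}
    signals |= {f"PC{k}": pc[k] for k in range(3)}
    signals |= {f"DEC{j}": dec[j] for j in range(8)}
    signals |= {f"ACC{k}": acc[k] for k in range(4)}
    signals |= {f"OUT{k}": out_bits[k] for k in range(4)}
    signals |= {f"SUM{k}": sums[k] for k in range(4)}
    netlist = c.build(signals)

    c0, c1 = _two_phase_clock(n_cycles)

    def behavior(name: str, in_per_cycle: np.ndarray) -> FixtureBehavior:
        in_per_cycle = np.asarray(in_per_cycle, dtype=np.int64) % 16
        bits = np.zeros((n_cycles, 4), dtype=np.uint8)
        for k in range(4):
            bits[:, k] = (in_per_cycle >> k) & 1
        stim = StimulusProgram(
            (clk0, clk1) + tuple(in_bits),
            np.column_stack([c0, c1, _per_cycle_to_steps(bits)]),
        )
        _, _, out = _microfsm_model(in_per_cycle)
        return FixtureBehavior(name=name, stimulus=stim,
                               expected_output=_register_stream(out),
                               success_prefix=64)

    cycles = np.arange(n_cycles)
    behaviors = [
        behavior("hold", np.full(n_cycles, 3)),
        behavior("ramp", (cycles // 8) % 16),
        behavior("toggle", np.where((cycles // 8) % 2 == 0, 5, 10)),
    ]
    reg = GroundTruthRegistry(
        fixture="microfsm",
        netlist=netlist,
        output_wires=tuple(out_bits),
        behaviors=behaviors,
        lfp_sites={
            "program_counter": (0.0, 0.0),
            "decoder": (6000.0, 0.0),
            "control": (12000.0, 0.0),
            "adder": (0.0, 6000.0),
            "accumulator": (6000.0, 6000.0),
            "output_register": (12000.0, 6000.0),
        },
        planted={"write_period_timesteps": 16},
    )
    reg.self_check()
    return reg


def make_fixture(name: str, seed: int = 0, **kwargs) -> GroundTruthRegistry:
    """Build a named fixture and verify its registry self-check.

    The self-check simulates every behavior un-lesioned and compares the
    output stream against the fixture's behavioral model; a mismatch aborts
    the build.
    """
    builders = {
        "adder4": _make_adder4,
        "shiftreg8": _make_shiftreg,
        "counter3_decoder": _make_counter3_decoder,
        "microfsm": _make_microfsm,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return builders[name](seed, **kwargs)
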