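"""Switch-level settling semantics, traces, lesions, and the oracle check."""

import numpy as np
import pytest

from neurochip.netlist import WireSpace, build_gate, compose
from neurochip.simulator import (
    Behavior,
    CircuitSimulator,
    Lesion,
    StimulusProgram,
    UnstableCircuitError,
    lesion_screen,
    resolve,
    run,
)

from _oracle import OracleUnstable, random_input_assignment, random_netlist, relax_settle


def _nand_netlist():
    space = WireSpace()
    a, b = space.input("A"), space.input("B")
    out = space.output("OUT")
    frag = build_gate(space, "nand2", (a, b), out)
    return compose(frag, signals={"A": a, "B": b, "OUT": out})


def _inverter_netlist():
    space = WireSpace()
    a = space.input("A")
    out = space.output("OUT")
    frag = build_gate(space, "not", (a,), out)
    return compose(frag, signals={"A": a, "OUT": out})


class TestResolve:
    @pytest.mark.parametrize("a, b, expected", [
        (0, 0, 1), (0, 1, 1), (1, 0, 1), (1, 1, 0),
    ])
    def test_nand_truth_table(self, a, b, expected):
        nl = _nand_netlist()
        state = resolve(nl, {nl.signals["A"]: a, nl.signals["B"]: b})
        assert state.wire_value[nl.signals["OUT"]] == expected

    def test_transistor_state_follows_gate(self):
        nl = _inverter_netlist()
        state = resolve(nl, {nl.signals["A"]: 1})
        (tid,) = [t.id for t in nl.transistors]
        assert state.transistor_on[tid]
        assert state.wire_value[nl.signals["OUT"]] == 0

    def test_isolated_charged_group_retains_value(self):
        # pass transistor: input D charges node S while CLK high; S keeps its
        # value after CLK drops even when D changes
        space = WireSpace()
        d, clk = space.input("D"), space.input("CLK")
        s = space.add(name="S")
        frag = build_gate(space, "not", (s,), space.add())  # a load on S
        from neurochip.netlist import Fragment

        passf = Fragment(space)
        passf.add_transistor(clk, d, s)
        nl = compose(frag, passf, signals={"D": d, "CLK": clk, "S": s})
        state = resolve(nl, {d: 1, clk: 1})
        assert state.wire_value[s] == 1
        held = resolve(nl, {d: 0, clk: 0, s: 1})
        assert held.wire_value[s] == 1

    def test_unstable_ring_reports_oscillating_wires(self):
        # an inverter driving its own gate cannot settle
        space = WireSpace()
        out = space.add(name="OUT")
        nl = compose(build_gate(space, "not", (out,), out))
        with pytest.raises(UnstableCircuitError, match="oscillating"):
            resolve(nl)

    @pytest.mark.parametrize("seed", range(40))
    def test_settling_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nl = random_netlist(rng)
        inputs = random_input_assignment(rng, nl)
        try:
            want_values, want_on = relax_settle(nl, inputs)
        except OracleUnstable:
            with pytest.raises(UnstableCircuitError):
                resolve(nl, inputs)
            return
        state = resolve(nl, inputs)
        assert state.wire_value == want_values
        assert state.transistor_on == {t: bool(v) for t, v in want_on.items()}


class TestRun:
    def test_four_stage_shift_register_delays_pattern(self):
        space = WireSpace()
        clk0, clk1 = space.input("CLK0"), space.input("CLK1")
        sin = space.input("SIN")
        frags = []
        d = sin
        outs = []
        for _ in range(4):
            q = space.add()
            frags.append(build_gate(space, "dff_2phase", (d, clk0, clk1), q))
            outs.append(q)
            d = q
        nl = compose(*frags, signals={"Q3": outs[-1]})
        pattern = [1, 0, 1, 1] + [0] * 8
        n_cycles = len(pattern)
        stim = StimulusProgram(
            (clk0, clk1, sin),
            np.column_stack([
                np.tile([1, 0], n_cycles),
                np.tile([0, 1], n_cycles),
                np.repeat(pattern, 2),
            ]),
        )
        trace = run(nl, stim)
        q3 = trace.wire_trace(outs[-1])
        # sampled at the end of each cycle; stages start high, and the
        # pattern appears on the last stage four cycles after it was driven
        per_cycle = q3[1::2]
        assert per_cycle[:3].tolist() == [1, 1, 1]
        assert per_cycle[3:8].tolist() == [1, 0, 1, 1, 0]

    def test_reruns_are_bit_identical(self):
        nl = _nand_netlist()
        rng = np.random.default_rng(0)
        stim = StimulusProgram(
            tuple(nl.input_ids),
            rng.integers(0, 2, size=(50, 2)).astype(np.uint8),
        )
        t1 = run(nl, stim)
        t2 = run(nl, stim)
        assert np.array_equal(t1.wire_values, t2.wire_values)
        assert np.array_equal(t1.transistor_on, t2.transistor_on)

    def test_stimulus_must_drive_exactly_the_inputs(self):
        nl = _nand_netlist()
        stim = StimulusProgram((nl.input_ids[0],), np.zeros((3, 1), dtype=np.uint8))
        with pytest.raises(Exception, match="missing"):
            run(nl, stim)

    def test_trace_round_trips_through_hdf5(self, tmp_path):
        nl = _inverter_netlist()
        stim = StimulusProgram(tuple(nl.input_ids),
                               np.array([[0], [1], [0]], dtype=np.uint8))
        trace = run(nl, stim)
        path = tmp_path / "trace.h5"
        trace.save(path)
        from neurochip.simulator import StateTrace

        again = StateTrace.load(path)
        assert np.array_equal(again.wire_values, trace.wire_values)
        assert again.wire_ids == trace.wire_ids


class TestLesions:
    def test_stuck_on_pulldown_forces_output_low(self):
        nl = _inverter_netlist()
        (tid,) = [t.id for t in nl.transistors]
        for a in (0, 1):
            state = resolve(nl, {nl.signals["A"]: a},
                            lesions=[Lesion(tid, "stuck_on")])
            assert state.wire_value[nl.signals["OUT"]] == 0

    def test_stuck_off_pulldown_forces_output_high(self):
        nl = _inverter_netlist()
        (tid,) = [t.id for t in nl.transistors]
        for a in (0, 1):
            state = resolve(nl, {nl.signals["A"]: a},
                            lesions=[Lesion(tid, "stuck_off")])
            assert state.wire_value[nl.signals["OUT"]] == 1

    def test_unknown_lesion_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            Lesion(0, "wobbly")

    def test_screen_partition_and_unreachable_transistor(self):
        # two independent inverters; the behavior only watches the first, so
        # the second inverter's transistor is outside every output cone
        space = WireSpace()
        a, b = space.input("A"), space.input("B")
        x, y = space.output("X"), space.add(name="Y")
        f1 = build_gate(space, "not", (a,), x)
        f2 = build_gate(space, "not", (b,), y)
        nl = compose(f1, f2, signals={"A": a, "B": b, "X": x})
        stim = StimulusProgram((a, b), np.array([[0, 0], [1, 1]], dtype=np.uint8))

        def watches_x(trace):
            return trace.wire_trace(x).tolist() == [1, 0]

        result = lesion_screen(nl, [Behavior("invert_a", stim, watches_x)])
        counts = result.counts
        assert sum(counts.values()) == nl.n_transistors
        assert result.disrupted[1] == frozenset()  # second inverter harmless
        assert result.disrupted[0] == frozenset({"invert_a"})

    def test_screen_requires_working_baseline(self):
        nl = _inverter_netlist()
        stim = StimulusProgram(tuple(nl.input_ids),
                               np.array([[1]], dtype=np.uint8))
        broken = Behavior("impossible", stim,
                          lambda trace: False)
        with pytest.raises(Exception, match="un-lesioned"):
            lesion_screen(nl, [broken])
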