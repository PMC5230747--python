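"""Netlist data model, builder, and canonical JSON round-trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurochip.netlist import (
    Netlist,
    NetlistError,
    NetlistParseError,
    NetlistValidationError,
    Transistor,
    Wire,
    WireSpace,
    build_gate,
    compose,
    netlist_from_json,
    netlist_to_json,
    read_netlist,
    write_netlist,
)

from _oracle import random_netlist


def minimal_netlist() -> Netlist:
    return Netlist(
        wires=(Wire(0, "VCC", False, "power"), Wire(1, "GND", False, "ground")),
        transistors=(),
    ).validate()


def inverter_netlist() -> Netlist:
    wires = (
        Wire(0, "VCC", False, "power"),
        Wire(1, "GND", False, "ground"),
        Wire(2, "A", False, "input"),
        Wire(3, "OUT", True, "output"),
    )
    return Netlist(wires=wires,
                   transistors=(Transistor(0, 2, 3, 1),)).validate()


class TestValidation:
    def test_inverter_is_smallest_valid_circuit(self):
        nl = inverter_netlist()
        assert nl.n_transistors == 1
        assert nl.power_id == 0 and nl.ground_id == 1

    def test_dangling_gate_reference_names_offending_id(self):
        wires = (Wire(0, None, False, "power"), Wire(1, None, False, "ground"))
        nl = Netlist(wires=wires, transistors=(Transistor(0, 99, 0, 1),))
        with pytest.raises(NetlistValidationError, match="99"):
            nl.validate()

    @pytest.mark.parametrize(
        "wires, message",
        [
            ((Wire(0, None, False, "power"),), "ground"),
            (
                (Wire(0, None, False, "power"), Wire(0, None, False, "ground")),
                "duplicate wire ids",
            ),
            (
                (Wire(0, None, True, "power"), Wire(1, None, False, "ground")),
                "pullup",
            ),
            (
                (Wire(0, None, False, "power"), Wire(1, None, False, "ground"),
                 Wire(2, None, False, "sideways")),
                "role",
            ),
        ],
    )
    def test_invariant_violations_are_rejected(self, wires, message):
        with pytest.raises(NetlistValidationError, match=message):
            Netlist(wires=wires, transistors=()).validate()

    def test_equal_channel_terminals_rejected(self):
        nl = Netlist(
            wires=(Wire(0, None, False, "power"), Wire(1, None, False, "ground")),
            transistors=(Transistor(0, 0, 1, 1),),
        )
        with pytest.raises(NetlistValidationError, match="c1 == c2"):
            nl.validate()

    def test_module_referencing_absent_transistor_rejected(self):
        nl = Netlist(
            wires=(Wire(0, None, False, "power"), Wire(1, None, False, "ground")),
            transistors=(),
            modules={"alu": frozenset({5})},
        )
        with pytest.raises(NetlistValidationError, match="alu"):
            nl.validate()


class TestJsonRoundTrip:
    def test_file_round_trip_is_bit_exact(self, tmp_path):
        nl = inverter_netlist()
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        write_netlist(nl, p1)
        write_netlist(read_netlist(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_field_is_a_parse_error_naming_the_field(self):
        obj = json.loads(netlist_to_json(inverter_netlist()))
        del obj["wires"][0]["pullup"]
        with pytest.raises(NetlistParseError, match="pullup"):
            netlist_from_json(json.dumps(obj))

    def test_wrongly_typed_field_is_a_parse_error(self):
        obj = json.loads(netlist_to_json(inverter_netlist()))
        obj["transistors"][0]["gate"] = "two"
        with pytest.raises(NetlistParseError, match="gate"):
            netlist_from_json(json.dumps(obj))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_netlists_round_trip_identically(self, seed):
        rng = np.random.default_rng(seed)
        nl = random_netlist(rng, n_transistors=int(rng.integers(0, 15)))
        text = netlist_to_json(nl)
        again = netlist_from_json(text)
        assert again == nl
        assert netlist_to_json(again) == text

    def test_fixture_registry_netlist_round_trips(self, adder4_registry):
        nl = adder4_registry.netlist
        assert netlist_from_json(netlist_to_json(nl)) == nl


class TestBuilder:
    def test_nand2_has_two_series_pulldowns_and_pullup_output(self):
        space = WireSpace()
        a, b = space.input("A"), space.input("B")
        out = space.output("OUT")
        frag = build_gate(space, "nand2", (a, b), out)
        assert len(frag.transistors) == 2
        assert space.wire(out).pullup
        t1, t2 = frag.transistors
        assert t1.gate == a and t2.gate == b
        assert t1.c1 == out and t1.c2 == t2.c1 and t2.c2 == space.ground

    def test_not_is_one_transistor_plus_pullup(self):
        space = WireSpace()
        a = space.input("A")
        out = space.output("OUT")
        frag = build_gate(space, "not", (a,), out)
        assert len(frag.transistors) == 1
        assert space.wire(out).pullup

    def test_unknown_kind_rejected(self):
        space = WireSpace()
        a = space.input("A")
        with pytest.raises(NetlistError, match="unknown gate kind"):
            build_gate(space, "xnor", (a,), space.output("OUT"))

    def test_cannot_drive_rails(self):
        space = WireSpace()
        a = space.input("A")
        with pytest.raises(NetlistError, match="ground"):
            build_gate(space, "not", (a,), space.ground)

    def test_compose_of_zero_fragments_gives_minimal_netlist(self):
        space = WireSpace()
        nl = compose(space=space)
        assert nl.n_transistors == 0
        assert {w.role for w in nl.wires} == {"power", "ground"}

    def test_compose_inverter_chain_is_two_transistor_buffer(self):
        space = WireSpace()
        a = space.input("A")
        mid = space.add()
        out = space.output("OUT")
        f1 = build_gate(space, "not", (a,), mid)
        f2 = build_gate(space, "not", (mid,), out)
        nl = compose(f1, f2, modules={"buffer": f1.transistors + f2.transistors})
        assert nl.n_transistors == 2
        assert [t.id for t in nl.transistors] == [0, 1]
        assert nl.modules["buffer"] == frozenset({0, 1})

    def test_compose_rejects_duplicated_fragment(self):
        space = WireSpace()
        a = space.input("A")
        frag = build_gate(space, "not", (a,), space.add())
        with pytest.raises(NetlistError, match="collision"):
            compose(frag, frag)

    def test_compose_rejects_mixed_namespaces(self):
        s1, s2 = WireSpace(), WireSpace()
        f1 = build_gate(s1, "not", (s1.input("A"),), s1.add())
        f2 = build_gate(s2, "not", (s2.input("A"),), s2.add())
        with pytest.raises(NetlistError, match="namespace"):
            compose(f1, f2)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_builder_outputs_always_validate(self, seed):
        rng = np.random.default_rng(seed)
        space = WireSpace()
        ins = [space.input(f"I{k}") for k in range(3)]
        frags = []
        for _ in range(int(rng.integers(1, 6))):
            kind = ["not", "nand2", "nor2"][int(rng.integers(0, 3))]
            n_in = 1 if kind == "not" else 2
            inputs = [int(rng.choice(ins)) for _ in range(n_in)]
            frags.append(build_gate(space, kind, inputs, space.add()))
        nl = compose(*frags)
        assert nl.validate() is nl
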