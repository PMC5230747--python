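"""Fixture self-consistency and surrogate-generator ground truth."""

import numpy as np
import pytest

from neurochip.simulator import CircuitSimulator
from neurochip.spiketrains import extract_spikes
from neurochip.synthetic import (
    GroundTruthRegistry,
    gen_block_stimulus,
    gen_planted_nmf,
    gen_planted_sbm,
    gen_tuned_spikes,
    gen_var,
    make_fixture,
)


class TestFixtures:
    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("cpu9000")

    def test_adder_exhaustive_truth_table_sample(self, adder4_registry):
        """Scalar output equals a + b on a sample of the exhaustive drive."""
        reg = adder4_registry
        sim = CircuitSimulator(reg.netlist)
        beh = reg.behavior("exhaustive")
        trace = sim.run(beh.stimulus.prefix(40))
        got = reg.output_stream(trace)
        assert np.array_equal(got, np.asarray(beh.expected_output)[:40])

    def test_counter_bits_have_doubling_spike_periods(self, counter3_registry,
                                                      counter3_trace):
        reg = counter3_registry
        spikes = extract_spikes(counter3_trace)
        periods = reg.planted["bit_spike_periods"]
        for k in range(3):
            wire = reg.netlist.signals[f"Q{k}"]
            col = counter3_trace.wire_trace(wire)
            times = np.flatnonzero(np.diff(col.astype(int)) == 1) + 1
            gaps = np.diff(times)
            assert np.all(gaps == periods[f"Q{k}"]), k

    def test_microfsm_behaviors_are_distinct(self, microfsm_registry):
        streams = [tuple(np.asarray(b.expected_output))
                   for b in microfsm_registry.behaviors]
        assert len(streams) == 3
        assert len(set(streams)) == 3

    def test_microfsm_modules_partition_annotated_transistors(self, microfsm_registry):
        nl = microfsm_registry.netlist
        covered = sorted(t for ids in nl.modules.values() for t in ids)
        assert covered == list(range(nl.n_transistors))

    def test_registry_round_trips_through_json(self, tmp_path, adder4_registry):
        adder4_registry.save(tmp_path)
        again = GroundTruthRegistry.load(tmp_path, "adder4")
        assert again.output_wires == adder4_registry.output_wires
        assert [b.name for b in again.behaviors] == \
            [b.name for b in adder4_registry.behaviors]
        beh0 = adder4_registry.behaviors[0]
        assert np.array_equal(again.behaviors[0].stimulus.values,
                              beh0.stimulus.values)
        again.self_check()

    def test_registry_self_check_catches_wrong_expectations(self, adder4_registry):
        import copy

        from neurochip.synthetic import SelfCheckError

        broken = copy.deepcopy(adder4_registry)
        broken.behaviors[0].expected_output = \
            np.asarray(broken.behaviors[0].expected_output) + 1
        with pytest.raises(SelfCheckError, match="diverges"):
            broken.self_check()


class TestGenVar:
    def test_zero_coefficients_give_white_noise_with_known_covariance(self):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        trials = gen_var(np.zeros((1, 2, 2)), cov, 20, 500, seed=0)
        stacked = trials.transpose(0, 2, 1).reshape(-1, 2)
        sample = np.cov(stacked.T)
        assert np.allclose(sample, cov, atol=0.1)

    def test_nonstationary_coefficients_rejected(self):
        coefs = np.zeros((1, 2, 2))
        coefs[0] = np.eye(2) * 1.01
        with pytest.raises(ValueError, match="non-stationary"):
            gen_var(coefs, np.eye(2), 2, 50)

    def test_seed_reproducibility(self):
        coefs = np.zeros((2, 2, 2))
        coefs[0, 0, 1] = 0.3
        a = gen_var(coefs, np.eye(2), 3, 100, seed=5)
        b = gen_var(coefs, np.eye(2), 3, 100, seed=5)
        assert np.array_equal(a, b)


class TestGenTunedSpikes:
    def test_zero_amplitude_is_homogeneous_at_baseline(self):
        stim = gen_block_stimulus(50_000, np.arange(11.0), seed=0)
        spikes = gen_tuned_spikes([(0.0, 5.0, 3.0, 1.0)], stim, seed=1,
                                  window=100)
        rate = len(spikes.events[0]) / 50_000 * 100
        se = np.sqrt(5.0 / 50_000) * 100 / 10  # binomial SE on the window rate
        assert rate == pytest.approx(5.0, abs=3 * max(se, 0.1))

    def test_rate_at_preferred_stimulus_is_peak_plus_baseline(self):
        a, b, mu, w = 8.0, 1.0, 5.0, 1.5
        stim = np.full(200_000, mu)
        spikes = gen_tuned_spikes([(a, b, mu, w)], stim, seed=2, window=100)
        p_hat = len(spikes.events[0]) / 200_000
        p_true = (a + b) / 100
        se = np.sqrt(p_true * (1 - p_true) / 200_000)
        assert abs(p_hat - p_true) < 3 * se

    def test_seed_reproducibility(self):
        stim = gen_block_stimulus(5000, np.arange(11.0), seed=3)
        a = gen_tuned_spikes([(8.0, 1.0, 5.0, 1.5)], stim, seed=4)
        b = gen_tuned_spikes([(8.0, 1.0, 5.0, 1.5)], stim, seed=4)
        assert np.array_equal(a.events[0], b.events[0])


class TestPlantedMatrices:
    def test_zero_noise_returns_exact_product(self):
        rng = np.random.default_rng(0)
        W = rng.random((10, 3))
        H = rng.random((3, 20))
        assert np.array_equal(gen_planted_nmf(W, H), W @ H)

    def test_negative_factors_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gen_planted_nmf(np.array([[-1.0]]), np.array([[1.0]]))

    def test_sbm_edge_density_matches_block_probabilities(self):
        rels, labels = gen_planted_sbm([40, 40], 0.6, 0.05, seed=1)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        offd = ~np.eye(80, dtype=bool)
        stack = rels.stacked()
        n_rel = stack.shape[0]
        within = stack[:, same].mean()
        across = stack[:, offd & ~same].mean()
        se_w = np.sqrt(0.6 * 0.4 / (same.sum() * n_rel))
        se_a = np.sqrt(0.05 * 0.95 / ((offd & ~same).sum() * n_rel))
        assert abs(within - 0.6) < 3 * se_w
        assert abs(across - 0.05) < 3 * se_a

    def test_sbm_seed_reproducibility(self):
        a, _ = gen_planted_sbm([10, 10], 0.5, 0.1, seed=2)
        b, _ = gen_planted_sbm([10, 10], 0.5, 0.1, seed=2)
        assert np.array_equal(a.stacked(), b.stacked())
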