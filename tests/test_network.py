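"""Tests for the probabilistic WTA network and both synapse flavours."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memstdp import (
    DevicePlasticityParams,
    HardwareSynapse,
    MemristorState,
    NetworkState,
    NeuronState,
    SoftwareSynapse,
    firing_probabilities,
    hardware_weight,
    measured_weight,
    membrane_potential,
    sample_winner,
    sigmoid,
    step,
    update_hardware_synapse,
    update_homeostasis,
    update_software_synapse,
)


def software_neuron(weights, theta=0.0, sigma_sw=0.0, sigma_meas=0.0):
    return NeuronState(
        [SoftwareSynapse(w, sigma_sw, sigma_meas) for w in weights], theta
    )


class TestMeasuredWeight:
    def test_noiseless_read_returns_true_weight(self, rng):
        syn = SoftwareSynapse(0.7, sigma_meas=0.0)
        assert measured_weight(syn, rng) == 0.7

    def test_reads_never_mutate_and_stay_in_five_sigma(self, rng):
        syn = SoftwareSynapse(0.3)  # default sigma_meas = 0.4
        draws = np.array([measured_weight(syn, rng) for _ in range(20_000)])
        assert syn.w == 0.3
        assert np.all(np.abs(draws - 0.3) <= 2.0 + 1e-12)  # 5 sigma = 2.0
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.3) < 3 * se


class TestHardwareWeight:
    def test_calibrated_map_endpoints_and_midpoint(self, rng):
        p = DevicePlasticityParams.calibrated(sigma_read=0.0)
        for g, expected in ((p.g_low, -2.2), (p.g_high, 2.2), (p.g_mid, 0.0)):
            syn = HardwareSynapse.calibrated(MemristorState(g, p))
            assert hardware_weight(syn, rng) == pytest.approx(expected, abs=1e-12)

    def test_inverse_map(self):
        p = DevicePlasticityParams.calibrated()
        syn = HardwareSynapse.calibrated(MemristorState(p.g_mid, p))
        assert syn.conductance_for_weight(2.2) == pytest.approx(p.g_high)
        assert syn.conductance_for_weight(-2.2) == pytest.approx(p.g_low)


class TestMembranePotential:
    def test_zero_pattern_returns_excitability(self, rng):
        neuron = software_neuron([1.0, -1.0, 0.5, 2.0], theta=0.37)
        assert membrane_potential(neuron, [0, 0, 0, 0], rng) == 0.37

    def test_dot_product_on_active_bits(self, rng):
        neuron = software_neuron([1.0, 1.0, 1.0, 1.0])
        assert membrane_potential(neuron, [0, 1, 1, 0], rng) == 2.0

    def test_excitability_shift_is_additive(self, rng):
        y = [1, 0, 1, 1]
        n0 = software_neuron([0.3, -0.2, 0.9, 0.1], theta=0.0)
        n1 = software_neuron([0.3, -0.2, 0.9, 0.1], theta=1.5)
        assert membrane_potential(n1, y, rng) == pytest.approx(
            membrane_potential(n0, y, rng) + 1.5
        )

    def test_dimension_mismatch_rejected(self, rng):
        neuron = software_neuron([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            membrane_potential(neuron, [1, 0], rng)


class TestFiringProbabilities:
    def test_equal_potentials_split_evenly(self):
        assert np.allclose(firing_probabilities([1.3, 1.3]), [0.5, 0.5])

    def test_two_class_logistic_identity(self):
        p = firing_probabilities([1.0, 0.0])
        assert p[0] == pytest.approx(sigmoid(1.0))
        assert p[1] == pytest.approx(sigmoid(-1.0))

    def test_large_gap_saturates(self):
        p = firing_probabilities([1000.0, 0.0])
        assert p[0] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        u0=st.floats(-1e4, 1e4),
        u1=st.floats(-1e4, 1e4),
    )
    def test_normalized_and_finite_for_any_potentials(self, u0, u1):
        p = firing_probabilities([u0, u1])
        assert np.all(np.isfinite(p))
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestSampleWinner:
    def test_degenerate_distribution(self, rng):
        assert all(sample_winner([1.0, 0.0], rng) == 0 for _ in range(100))

    def test_fair_coin_binomial(self, rng):
        wins = sum(sample_winner([0.5, 0.5], rng) for _ in range(100_000))
        se = math.sqrt(0.25 * 100_000)
        assert abs(wins - 50_000) < 3 * se


class TestSoftwareUpdate:
    def test_step_from_zero_weight(self, rng):
        for pre, expected in ((1, 0.015), (0, -0.015)):
            syn = SoftwareSynapse(0.0, sigma_sw=0.0)
            update_software_synapse(syn, pre, 0.03, rng)
            assert syn.w == pytest.approx(expected)

    def test_weights_clipped_to_operational_range(self, rng):
        syn = SoftwareSynapse(2.199, sigma_sw=0.0)
        for _ in range(100):
            update_software_synapse(syn, 1, 0.5, rng)
        assert syn.w == 2.2

    def test_switching_noise_clipped_to_five_sigma(self, rng):
        syn = SoftwareSynapse(0.0)  # sigma_sw = 0.04
        deltas = []
        for _ in range(5000):
            w0 = syn.w
            update_software_synapse(syn, 1, 0.0, rng)  # eta 0: pure noise
            deltas.append(syn.w - w0)
        assert np.all(np.abs(deltas) <= 0.2 + 1e-12)

    @pytest.mark.parametrize("q", [0.2, 0.5, 0.8])
    def test_fixed_point_is_logit_of_pre_rate(self, q):
        """Under Bernoulli(q) PRE bits and forced POST, the noiseless rule
        settles where sigma(w) = q, i.e. w* = log(q / (1 - q))."""
        rng = np.random.default_rng(17)
        syn = SoftwareSynapse(0.0, sigma_sw=0.0)
        history = np.empty(50_000)
        for i in range(history.size):
            update_software_synapse(syn, int(rng.random() < q), 0.03, rng)
            history[i] = syn.w
        assert history[-30_000:].mean() == pytest.approx(
            math.log(q / (1 - q)), abs=0.1
        )


class TestHardwareUpdate:
    def test_pre_one_potentiates_pre_zero_depresses(self, quiet_params, rng):
        for pre, sign in ((1, 1), (0, -1)):
            syn = HardwareSynapse.calibrated(
                MemristorState(quiet_params.g_mid, quiet_params)
            )
            g0 = syn.device.g
            update_hardware_synapse(syn, pre, rng)
            assert sign * (syn.device.g - g0) > 0

    def test_expected_update_balance_is_sigmoidal_in_weight(self, quiet_params, rng):
        """The device's LTP/LTD balance, expressed through the calibrated
        weight map, matches the software rule's sigma(w) within 5% over
        w in [-2, 2]: the hardware update is proportional to (pre - sigma(w))."""
        for w in np.linspace(-2.0, 2.0, 41):
            syn = HardwareSynapse.calibrated(
                MemristorState(quiet_params.g_mid, quiet_params)
            )
            g = syn.conductance_for_weight(w)
            up = HardwareSynapse(MemristorState(g, quiet_params), syn.alpha, syn.beta)
            down = HardwareSynapse(MemristorState(g, quiet_params), syn.alpha, syn.beta)
            update_hardware_synapse(up, 1, rng)
            update_hardware_synapse(down, 0, rng)
            dw_ltp = up.w - w
            dw_ltd = down.w - w
            balance = -dw_ltd / (dw_ltp - dw_ltd)
            assert balance == pytest.approx(sigmoid(w), abs=0.05)


class TestHomeostasis:
    def test_single_step_magnitude(self):
        for fired, expected in ((0, 0.015), (1, -0.015)):
            neuron = software_neuron([0.0] * 4)
            update_homeostasis(neuron, fired)
            assert neuron.theta == pytest.approx(expected)

    def test_balanced_firing_leaves_theta_stationary(self, rng):
        neuron = software_neuron([0.0] * 4)
        n = 100_000
        for fired in (rng.random(n) < 0.5).astype(int):
            update_homeostasis(neuron, int(fired))
        # mean drift per step ~ eta_theta * (0.5 - rate) ~ 0
        assert abs(neuron.theta / n) < 5e-4


class TestStep:
    def hybrid_network(self, sigma_meas=0.4, sigma_read=None):
        p = DevicePlasticityParams.calibrated(
            **({} if sigma_read is None else {"sigma_read": sigma_read})
        )
        hw = NeuronState(
            [HardwareSynapse.calibrated(MemristorState(p.g_mid, p))
             for _ in range(4)]
        )
        sw = NeuronState(
            [SoftwareSynapse(0.0, 0.04, sigma_meas) for _ in range(4)]
        )
        return NetworkState([hw, sw])

    def test_exactly_one_winner_and_counts_conserved(self, rng):
        net = self.hybrid_network()
        winners = []
        for _ in range(300):
            w, rec = step(net, [0, 1, 1, 0], rng)
            assert w in (0, 1)
            assert rec.p[0] + rec.p[1] == pytest.approx(1.0, abs=1e-12)
            winners.append(w)
        assert len(winners) == 300
        assert winners.count(0) + winners.count(1) == 300

    def test_symmetric_start_is_a_fair_coin(self, rng):
        net = self.hybrid_network(sigma_meas=0.0, sigma_read=0.0)
        _, rec = step(net, [0, 1, 1, 0], rng)
        assert rec.p[0] == pytest.approx(0.5)

    def test_loser_bank_is_untouched(self, rng):
        net = self.hybrid_network()
        for _ in range(50):
            before = [
                [s.w for s in neuron.synapses] for neuron in net.neurons
            ]
            w, _ = step(net, [1, 0, 0, 1], rng)
            loser = 1 - w
            assert [s.w for s in net.neurons[loser].synapses] == before[loser]

    def test_same_seed_replays_identical_trajectory(self):
        records = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            net = self.hybrid_network()
            records.append([step(net, [0, 1, 1, 0], rng)[1] for _ in range(100)])
        assert records[0] == records[1]
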