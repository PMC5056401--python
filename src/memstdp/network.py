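"""Probabilistic winner-take-all network with hybrid synapse banks.

Two stochastic spiking neurons, four binary inputs each. One neuron's
synapse bank may be device-backed (memristive), the other's implemented in
software. At every input event each neuron computes a membrane potential

    U_i = v_i . y + theta_i,

where ``v_i`` are the *measured* weights (underlying weight plus fresh
measurement/read noise) and ``theta_i`` an adaptive excitability. Exactly one
neuron wins the competition, with probability softmax(U); the winner's
synapses undergo STDP (software rule ``dw = eta * (pre - sigma(w)) + noise``
or a device LTP/LTD event), and both excitabilities follow a homeostatic
rule that pulls long-run firing rates toward 1/n_neurons.

Measured weights never mutate the underlying weight; switching variability
is a separate additive term on each software update, mirroring the device's
cycle-to-cycle variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .device import (
    DevicePlasticityParams,
    MemristorState,
    PlasticityEvent,
    apply_event,
    read_conductance,
)

__all__ = [
    "WEIGHT_LIMIT",
    "SoftwareSynapse",
    "HardwareSynapse",
    "NeuronState",
    "NetworkState",
    "StepRecord",
    "sigmoid",
    "measured_weight",
    "hardware_weight",
    "observed_weight",
    "observed_weights",
    "membrane_potential",
    "firing_probabilities",
    "sample_winner",
    "update_software_synapse",
    "update_hardware_synapse",
    "update_homeostasis",
    "step",
]

#: Abstract weight corresponding to the device bounds: g_low -> -2.2,
#: g_high -> +2.2. Software weights are clipped to the same range so the
#: two banks stay comparable.
WEIGHT_LIMIT = 2.2


def sigmoid(x):
    """Logistic function ``sigma(x) = 1 / (1 + exp(-x))``."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def _clipped_normal(rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0.0:
        return 0.0
    v = rng.normal(0.0, sigma)
    lim = 5.0 * sigma
    return max(-lim, min(lim, v))


@dataclass
class SoftwareSynapse:
    """Software synapse: true weight plus its two corruption amplitudes.

    ``sigma_sw`` is the switching-variability s.d. added to every update;
    ``sigma_meas`` the measurement-noise s.d. added to every read. Both in
    abstract-weight units, both applied clipped to +-5 sigma.
    """

    w: float = 0.0
    sigma_sw: float = 0.04
    sigma_meas: float = 0.4

    def __post_init__(self) -> None:
        if self.sigma_sw < 0 or self.sigma_meas < 0:
            raise ValueError("noise s.d. must be non-negative")


@dataclass
class HardwareSynapse:
    """Device-backed synapse with its calibrated conductance-to-weight map.

    The map is linear, ``w = alpha * g + beta``, calibrated so that
    ``g_low -> -weight_limit`` and ``g_high -> +weight_limit``.
    """

    device: MemristorState
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be strictly positive")

    @classmethod
    def calibrated(
        cls, device: MemristorState, weight_limit: float = WEIGHT_LIMIT
    ) -> "HardwareSynapse":
        p = device.params
        alpha = 2.0 * weight_limit / (p.g_high - p.g_low)
        beta = -weight_limit - alpha * p.g_low
        return cls(device=device, alpha=alpha, beta=beta)

    @property
    def w(self) -> float:
        """Noiseless mapped weight ``alpha * g + beta``."""
        return self.alpha * self.device.g + self.beta

    def conductance_for_weight(self, w: float) -> float:
        """Inverse map: conductance that realizes abstract weight ``w``."""
        return (w - self.beta) / self.alpha


def measured_weight(syn: SoftwareSynapse, rng: np.random.Generator) -> float:
    """Measured weight ``v = w + Normal(0, sigma_meas)`` clipped to +-5 sigma.

    The underlying weight is left untouched.
    """
    return syn.w + _clipped_normal(rng, syn.sigma_meas)


def hardware_weight(syn: HardwareSynapse, rng: np.random.Generator) -> float:
    """Mapped weight from one noisy conductance read."""
    return syn.alpha * read_conductance(syn.device, rng, n_reads=1) + syn.beta


def observed_weight(syn, rng: np.random.Generator) -> float:
    """Noise-corrupted weight of either synapse flavour."""
    if isinstance(syn, SoftwareSynapse):
        return measured_weight(syn, rng)
    return hardware_weight(syn, rng)


@dataclass
class NeuronState:
    """One WTA neuron: an ordered synapse bank plus its excitability."""

    synapses: list
    theta: float = 0.0
    eta_theta: float = 0.03

    def underlying_weights(self) -> np.ndarray:
        """True weights of the bank, with no fresh noise."""
        return np.array([s.w for s in self.synapses], dtype=float)


@dataclass
class NetworkState:
    """The full network: neurons, software learning rate, event counter."""

    neurons: list
    eta: float = 0.03
    weight_limit: float = WEIGHT_LIMIT
    plasticity_on_measured: bool = False
    t: int = 0

    def __post_init__(self) -> None:
        sizes = {len(n.synapses) for n in self.neurons}
        if len(sizes) > 1:
            raise ValueError("all neurons must have equal bank size")


@dataclass(frozen=True)
class StepRecord:
    """Log of one WTA event."""

    t: int
    y: tuple
    winner: int
    U: tuple
    p: tuple
    theta: tuple
    weights: tuple


def observed_weights(neuron: NeuronState, rng: np.random.Generator) -> np.ndarray:
    """Fresh noise-corrupted weights for the whole bank (one draw each)."""
    return np.array([observed_weight(s, rng) for s in neuron.synapses])


def membrane_potential(neuron: NeuronState, y, rng: np.random.Generator) -> float:
    """``U = v . y + theta`` with fresh measurement/read noise on the bank."""
    y = np.asarray(y, dtype=float)
    if y.size != len(neuron.synapses):
        raise ValueError(
            f"pattern has {y.size} bits but the bank holds "
            f"{len(neuron.synapses)} synapses"
        )
    return float(observed_weights(neuron, rng) @ y + neuron.theta)


def firing_probabilities(potentials) -> np.ndarray:
    """Softmax of the membrane potentials, computed stably.

    ``p_i = exp(U_i) / sum_j exp(U_j)`` after subtracting the maximum;
    the result sums to 1 exactly up to float rounding and never overflows.
    """
    u = np.asarray(potentials, dtype=float)
    z = np.exp(u - np.max(u))
    return z / np.sum(z)


def sample_winner(p, rng: np.random.Generator) -> int:
    """Sample exactly one winner index from the firing probabilities."""
    p = np.asarray(p, dtype=float)
    c = np.cumsum(p)
    return int(np.searchsorted(c / c[-1], rng.random(), side="right"))


def update_software_synapse(
    syn: SoftwareSynapse,
    pre: int,
    eta: float,
    rng: np.random.Generator,
    weight_limit: float = WEIGHT_LIMIT,
    f_input: float | None = None,
) -> SoftwareSynapse:
    """Winner-synapse software STDP update.

    ``w <- w + eta * (pre - sigma(w)) + w_var`` with
    ``w_var ~ Normal(0, sigma_sw)`` clipped to +-5 sigma, then clipped to the
    operational weight range. By default the weight-dependent factor uses the
    true underlying ``w``; pass ``f_input`` to evaluate it at a measured
    value instead.
    """
    x = syn.w if f_input is None else f_input
    dw = eta * (pre - sigmoid(x)) + _clipped_normal(rng, syn.sigma_sw)
    syn.w = max(-weight_limit, min(weight_limit, syn.w + dw))
    return syn


def update_hardware_synapse(
    syn: HardwareSynapse, pre: int, rng: np.random.Generator
) -> HardwareSynapse:
    """Winner-synapse device update: dispatch an STDP event with POST = 1.

    ``pre = 1`` triggers a device LTP step, ``pre = 0`` an LTD step; the step
    magnitude is inherently set by the device's own state-dependent rule.
    """
    syn.device = apply_event(syn.device, PlasticityEvent(int(pre), 1), rng)
    return syn


def update_homeostasis(
    neuron: NeuronState, fired: int, n_neurons: int = 2
) -> NeuronState:
    """``theta <- theta + eta_theta * (1/n_neurons - fired)``.

    Raises the excitability of silent neurons and lowers that of frequent
    winners, so long-run firing rates equalize at 1/n_neurons.
    """
    if fired not in (0, 1):
        raise ValueError("fired must be binary")
    neuron.theta += neuron.eta_theta * (1.0 / n_neurons - fired)
    return neuron


def step(
    network: NetworkState, y, rng: np.random.Generator
) -> tuple[int, StepRecord]:
    """One WTA event: compete, fire exactly one neuron, adapt.

    Fresh measurement/read noise is drawn once per synapse to form both
    membrane potentials; the winner's synapses receive ``(PRE=y_j, POST=1)``
    plasticity (losers receive nothing, which is plasticity-neutral); both
    neurons' excitabilities then follow the homeostatic rule. The returned
    record logs potentials, probabilities, winner, post-update underlying
    weights and excitabilities.
    """
    y = np.asarray(y, dtype=np.int64)
    n_neurons = len(network.neurons)
    obs = [observed_weights(neuron, rng) for neuron in network.neurons]
    potentials = np.array(
        [float(o @ y + neuron.theta) for o, neuron in zip(obs, network.neurons)]
    )
    probs = firing_probabilities(potentials)
    winner = sample_winner(probs, rng)

    win_neuron = network.neurons[winner]
    for j, syn in enumerate(win_neuron.synapses):
        if isinstance(syn, SoftwareSynapse):
            f_in = obs[winner][j] if network.plasticity_on_measured else None
            update_software_synapse(
                syn, int(y[j]), network.eta, rng, network.weight_limit, f_in
            )
        else:
            update_hardware_synapse(syn, int(y[j]), rng)
    for i, neuron in enumerate(network.neurons):
        update_homeostasis(neuron, int(i == winner), n_neurons)

    record = StepRecord(
        t=network.t,
        y=tuple(int(b) for b in y),
        winner=winner,
        U=tuple(float(u) for u in potentials),
        p=tuple(float(q) for q in probs),
        theta=tuple(float(n.theta) for n in network.neurons),
        weights=tuple(
            float(w) for n in network.neurons for w in n.underlying_weights()
        ),
    )
    network.t += 1
    return winner, record
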