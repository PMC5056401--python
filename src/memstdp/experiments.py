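"""Reproducible experiment protocols: learning, reversal, reporting.

A learning run presents 1,200 noisy 4-bit patterns to the hybrid 2-neuron
WTA network with all weights initialized near zero (software weights at 0,
device conductances at the map midpoint) and excitabilities at 0. A reversal
run continues from a previous run's final state: hardware synapses and
excitabilities carry over untouched, while the software bank is re-initialized
at the extreme weights of the prototype the hardware neuron had claimed --
which instantly reverses the pattern-to-neuron mapping and drives the
memristive synapses to re-specialize on the opposite prototype.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .device import DevicePlasticityParams, MemristorState
from .network import (
    WEIGHT_LIMIT,
    HardwareSynapse,
    NetworkState,
    NeuronState,
    SoftwareSynapse,
    step,
)
from .patterns import (
    PROTOTYPES,
    classification_accuracy,
    fire_count_histogram,
    generate_pattern,
    specialization,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "build_network",
    "run_learning",
    "run_reversal",
    "summarize_run",
]


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of one WTA run.

    Defaults are the reference operating point: learning rates
    ``eta = eta_theta = 0.03``, software noise ``sigma_sw = 0.04`` and
    ``sigma_meas = 0.4`` (abstract weight), 1,200 events of 10%-corrupted
    patterns, one hardware and one software bank of four synapses.
    """

    protocol: str = "learn"
    n_events: int = 1200
    seed: int = 0
    flip_prob: float = 0.1
    eta: float = 0.03
    eta_theta: float = 0.03
    sigma_sw: float = 0.04
    sigma_meas: float = 0.4
    weight_limit: float = WEIGHT_LIMIT
    banks: tuple = ("hardware", "software")
    device: dict | None = None
    software_weight_init: tuple | None = None
    burn_in: int = 0
    metric_window: int = 41

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        for bank in self.banks:
            if bank not in ("hardware", "software"):
                raise ValueError(f"unknown bank kind {bank!r}")
        if self.device is None:
            # normalize so that configs round-trip through files unchanged
            object.__setattr__(
                self,
                "device",
                DevicePlasticityParams.calibrated(
                    weight_limit=self.weight_limit
                ).to_dict(),
            )

    def device_params(self) -> DevicePlasticityParams:
        if self.device is None:
            return DevicePlasticityParams.calibrated(
                weight_limit=self.weight_limit
            )
        return DevicePlasticityParams.from_dict(self.device)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "n_events": self.n_events,
            "seed": self.seed,
            "flip_prob": self.flip_prob,
            "eta": self.eta,
            "eta_theta": self.eta_theta,
            "sigma_sw": self.sigma_sw,
            "sigma_meas": self.sigma_meas,
            "weight_limit": self.weight_limit,
            "banks": list(self.banks),
            "device": self.device_params().to_dict(),
            "software_weight_init": (
                list(self.software_weight_init)
                if self.software_weight_init is not None
                else None
            ),
            "burn_in": self.burn_in,
            "metric_window": self.metric_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "banks" in d and d["banks"] is not None:
            d["banks"] = tuple(d["banks"])
        if d.get("software_weight_init") is not None:
            d["software_weight_init"] = tuple(d["software_weight_init"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def build_network(config: RunConfig) -> NetworkState:
    """Fresh network per config: weights near 0, excitabilities at 0.

    Hardware devices start at the conductance midpoint, whose mapped weight
    is exactly 0 under the calibrated map; software weights start at the
    configured init (default 0).
    """
    dev_params = config.device_params()
    n_inputs = 4
    init = config.software_weight_init or tuple(0.0 for _ in range(n_inputs))
    neurons = []
    for bank in config.banks:
        if bank == "hardware":
            syns = [
                HardwareSynapse.calibrated(
                    MemristorState(dev_params.g_mid, dev_params),
                    config.weight_limit,
                )
                for _ in range(n_inputs)
            ]
        else:
            syns = [
                SoftwareSynapse(float(w), config.sigma_sw, config.sigma_meas)
                for w in init
            ]
        neurons.append(NeuronState(syns, theta=0.0, eta_theta=config.eta_theta))
    return NetworkState(
        neurons, eta=config.eta, weight_limit=config.weight_limit
    )


def _run(network: NetworkState, config: RunConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    for _ in range(config.burn_in):
        sample = generate_pattern(rng, config.flip_prob)
        step(network, sample.y, rng)
    rows = []
    for _ in range(config.n_events):
        sample = generate_pattern(rng, config.flip_prob)
        _, rec = step(network, sample.y, rng)
        s = specialization(network)
        row = {
            "t": rec.t,
            "prototype": sample.prototype,
            "pattern": "".join(str(b) for b in rec.y),
            "group": sample.group,
            "winner": rec.winner,
            "U0": rec.U[0],
            "U1": rec.U[1],
            "p0": rec.p[0],
            "p1": rec.p[1],
            "theta0": rec.theta[0],
            "theta1": rec.theta[1],
        }
        for k, w in enumerate(rec.weights):
            row[f"w{k}"] = w
        row["S0"] = float(s[0])
        row["S1"] = float(s[1])
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_run(records: pd.DataFrame, window: int = 41) -> dict:
    """Endpoint metrics of a run: specialization, accuracy, histograms.

    The metric window is clamped to the run length for short runs.
    """
    window = min(window, len(records))
    acc_final = classification_accuracy(records, window, "final")
    acc_initial = classification_accuracy(records, window, "initial")
    hist_final = fire_count_histogram(records, window, "final")
    hist_initial = fire_count_histogram(records, window, "initial")
    last = records.iloc[-1]
    return {
        "n_events": int(len(records)),
        "S_final": [float(last["S0"]), float(last["S1"])],
        "assignment": {str(k): v for k, v in acc_final["assignment"].items()},
        "accuracy_final": {str(k): v for k, v in acc_final["accuracy"].items()},
        "accuracy_initial": {
            str(k): v for k, v in acc_initial["accuracy"].items()
        },
        "fire_counts": {
            str(i): int((records["winner"] == i).sum()) for i in (0, 1)
        },
        "histogram_final": {
            g: [int(c) for c in hist_final.loc[g]] for g in hist_final.index
        },
        "histogram_initial": {
            g: [int(c) for c in hist_initial.loc[g]]
            for g in hist_initial.index
        },
    }


@dataclass
class RunResult:
    """Everything one run produced: config echo, records, final state, summary."""

    config: RunConfig
    records: pd.DataFrame
    network: NetworkState
    summary: dict

    def hardware_neuron_index(self) -> int | None:
        for i, neuron in enumerate(self.network.neurons):
            if isinstance(neuron.synapses[0], HardwareSynapse):
                return i
        return None

    def save(self, outdir) -> Path:
        """Write records.csv, summary.json, state.json, config.yaml, run.log."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))
        (out / "state.json").write_text(
            json.dumps(_state_to_dict(self.network), indent=2)
        )
        cfg = self.config.to_dict()
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
        log_lines = [f"protocol = {self.config.protocol}"]
        log_lines += [f"{k} = {v}" for k, v in sorted(cfg.items()) if k != "protocol"]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return out

    @classmethod
    def load(cls, rundir) -> "RunResult":
        out = Path(rundir)
        config = RunConfig.from_dict(
            yaml.safe_load((out / "config.yaml").read_text())
        )
        records = pd.read_csv(
            out / "records.csv", dtype={"pattern": str, "prototype": str}
        )
        network = _state_from_dict(
            json.loads((out / "state.json").read_text())
        )
        summary = json.loads((out / "summary.json").read_text())
        return cls(config, records, network, summary)


def _state_to_dict(network: NetworkState) -> dict:
    neurons = []
    for neuron in network.neurons:
        if isinstance(neuron.synapses[0], HardwareSynapse):
            neurons.append(
                {
                    "kind": "hardware",
                    "theta": neuron.theta,
                    "eta_theta": neuron.eta_theta,
                    "alpha": neuron.synapses[0].alpha,
                    "beta": neuron.synapses[0].beta,
                    "g": [s.device.g for s in neuron.synapses],
                    "params": neuron.synapses[0].device.params.to_dict(),
                }
            )
        else:
            neurons.append(
                {
                    "kind": "software",
                    "theta": neuron.theta,
                    "eta_theta": neuron.eta_theta,
                    "w": [s.w for s in neuron.synapses],
                    "sigma_sw": neuron.synapses[0].sigma_sw,
                    "sigma_meas": neuron.synapses[0].sigma_meas,
                }
            )
    return {
        "eta": network.eta,
        "weight_limit": network.weight_limit,
        "t": network.t,
        "neurons": neurons,
    }


def _state_from_dict(d: dict) -> NetworkState:
    neurons = []
    for nd in d["neurons"]:
        if nd["kind"] == "hardware":
            params = DevicePlasticityParams.from_dict(nd["params"])
            syns = [
                HardwareSynapse(
                    MemristorState(g, params), nd["alpha"], nd["beta"]
                )
                for g in nd["g"]
            ]
        else:
            syns = [
                SoftwareSynapse(w, nd["sigma_sw"], nd["sigma_meas"])
                for w in nd["w"]
            ]
        neurons.append(
            NeuronState(syns, theta=nd["theta"], eta_theta=nd["eta_theta"])
        )
    net = NetworkState(
        neurons, eta=d["eta"], weight_limit=d["weight_limit"]
    )
    net.t = d["t"]
    return net


def run_learning(config: RunConfig) -> RunResult:
    """Full unsupervised learning run from a near-zero initialization."""
    network = build_network(config)
    records = _run(network, config)
    summary = summarize_run(records, config.metric_window)
    summary["seed"] = config.seed
    return RunResult(config, records, network, summary)


def run_reversal(config: RunConfig, previous: RunResult) -> RunResult:
    """Reversal run continuing from a previous run's final state.

    Hardware synapses and excitabilities carry over; software weights are
    re-initialized at the extremes (+-weight_limit) matching the prototype
    the hardware neuron had specialized on, which flips the preferred
    pattern-to-neuron mapping and pushes the memristive synapses toward the
    opposite prototype.
    """
    network = copy.deepcopy(previous.network)
    hw_idx = None
    for i, neuron in enumerate(network.neurons):
        if isinstance(neuron.synapses[0], HardwareSynapse):
            hw_idx = i
    if hw_idx is None:
        raise ValueError("reversal requires a hardware bank in the previous run")
    tail = previous.records.tail(max(1, len(previous.records) // 4))
    hw_proto = "1001" if float(tail[f"S{hw_idx}"].mean()) > 0 else "0110"
    target_bits = PROTOTYPES[hw_proto]
    lim = config.weight_limit
    for neuron in network.neurons:
        if isinstance(neuron.synapses[0], SoftwareSynapse):
            for syn, bit in zip(neuron.synapses, target_bits):
                syn.w = lim if bit else -lim
                syn.sigma_sw = config.sigma_sw
                syn.sigma_meas = config.sigma_meas
    network.eta = config.eta
    config = replace(config, protocol="reverse")
    records = _run(network, config)
    summary = summarize_run(records, config.metric_window)
    summary["seed"] = config.seed
    summary["reversed_from_prototype"] = hw_proto
    return RunResult(config, records, network, summary)
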