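"""Input patterns, pattern-group taxonomy, and analysis metrics.

Inputs are 4-bit vectors drawn equiprobably from the prototypes 0110 and
1001, with each bit independently flipped with probability 0.1. Patterns are
grouped by Hamming distance to the prototypes: the prototype itself,
distance-1 variants (the delta groups), and the six distance-2 patterns that
are equidistant from both prototypes (ambiguous; the prototypes differ in
all four positions, so d0 + d1 = 4 always).

Metrics: per-neuron specialization ``S_i = p_i(1001) - p_i(0110)`` computed
from the noiseless weights (it describes the neuron's intrinsic preference,
not a particular noisy read), fire-count histograms over an initial or final
window, per-neuron classification accuracy on its assigned pattern group,
and exponential-fit noise estimates for weight traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characterization import fit_saturating_exponential
from .network import NetworkState, firing_probabilities

__all__ = [
    "PROTOTYPES",
    "PROTOTYPE_NAMES",
    "GROUPS",
    "PatternSample",
    "generate_pattern",
    "generate_patterns",
    "classify_group",
    "specialization",
    "fire_count_histogram",
    "classification_accuracy",
    "weight_noise_estimate",
]

PROTOTYPE_NAMES = ("0110", "1001")
PROTOTYPES = {
    "0110": np.array([0, 1, 1, 0], dtype=np.int64),
    "1001": np.array([1, 0, 0, 1], dtype=np.int64),
}
GROUPS = ("proto_0110", "delta_0110", "proto_1001", "delta_1001", "ambiguous")


@dataclass(frozen=True)
class PatternSample:
    """Prototype label plus the corrupted 4-bit vector actually presented."""

    prototype: str
    y: tuple
    group: str


def classify_group(y) -> str:
    """Group label of a 4-bit pattern by Hamming distance to the prototypes.

    Distance 0 from a prototype -> ``proto_X``; distance 1 -> ``delta_X``;
    otherwise (equidistant, distance 2 from both) -> ``ambiguous``.
    """
    y = np.asarray(y, dtype=np.int64)
    if y.shape != (4,) or not np.isin(y, (0, 1)).all():
        raise ValueError("pattern must be a 4-bit binary vector")
    d0 = int(np.sum(y != PROTOTYPES["0110"]))
    d1 = int(np.sum(y != PROTOTYPES["1001"]))
    if d0 == 0:
        return "proto_0110"
    if d1 == 0:
        return "proto_1001"
    if d0 == 1:
        return "delta_0110"
    if d1 == 1:
        return "delta_1001"
    return "ambiguous"


def generate_pattern(rng: np.random.Generator, flip_prob: float = 0.1) -> PatternSample:
    """Draw a prototype equiprobably and flip each bit with ``flip_prob``."""
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must lie in [0, 1]")
    name = PROTOTYPE_NAMES[int(rng.integers(0, 2))]
    flips = rng.random(4) < flip_prob
    y = np.bitwise_xor(PROTOTYPES[name], flips.astype(np.int64))
    return PatternSample(name, tuple(int(b) for b in y), classify_group(y))


def generate_patterns(
    rng: np.random.Generator, n: int, flip_prob: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized batch draw: (prototype indices into PROTOTYPE_NAMES, n x 4 bits)."""
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must lie in [0, 1]")
    idx = rng.integers(0, 2, size=n)
    protos = np.stack([PROTOTYPES[PROTOTYPE_NAMES[i]] for i in (0, 1)])[idx]
    flips = (rng.random((n, 4)) < flip_prob).astype(np.int64)
    return idx, np.bitwise_xor(protos, flips)


def specialization(network: NetworkState) -> np.ndarray:
    """Per-neuron specialization ``S_i = p_i(1001) - p_i(0110)``.

    Firing probabilities are computed from the noiseless underlying weights
    and current excitabilities (no fresh measurement noise), so S reflects
    the neurons' intrinsic pattern preferences. Bounded in [-1, 1]; for two
    neurons ``S_0 = -S_1`` exactly because probabilities sum to 1 per
    pattern.
    """
    probs = {}
    for name in PROTOTYPE_NAMES:
        y = PROTOTYPES[name]
        potentials = [
            float(neuron.underlying_weights() @ y + neuron.theta)
            for neuron in network.neurons
        ]
        probs[name] = firing_probabilities(potentials)
    return probs["1001"] - probs["0110"]


def _window_slice(df: pd.DataFrame, window: int, end: str) -> pd.DataFrame:
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(df):
        raise ValueError(f"window {window} exceeds run length {len(df)}")
    if end == "initial":
        return df.head(window)
    if end == "final":
        return df.tail(window)
    raise ValueError("end must be 'initial' or 'final'")


def fire_count_histogram(
    records: pd.DataFrame, window: int = 41, end: str = "final"
) -> pd.DataFrame:
    """Winner counts per (neuron, pattern group) over a run window.

    ``records`` is a run frame with ``group`` and ``winner`` columns. Returns
    a frame indexed by group with one column per neuron; entries sum to
    ``window`` (one winner per event).
    """
    part = _window_slice(records, window, end)
    neurons = sorted(records["winner"].unique()) if len(records) else [0, 1]
    neurons = sorted(set(neurons) | {0, 1})
    out = pd.DataFrame(
        0, index=list(GROUPS), columns=[f"neuron{i}" for i in neurons]
    )
    for _, row in part.iterrows():
        out.loc[row["group"], f"neuron{int(row['winner'])}"] += 1
    return out


def _assignments(records: pd.DataFrame) -> dict:
    """Neuron -> prototype from the sign of mean S over the final quarter."""
    tail = records.tail(max(1, len(records) // 4))
    out = {}
    for i in (0, 1):
        out[i] = "1001" if float(tail[f"S{i}"].mean()) > 0 else "0110"
    return out


def classification_accuracy(
    records: pd.DataFrame, window: int = 41, end: str = "final"
) -> dict:
    """Per-neuron win fraction on its assigned pattern group in a window.

    Each neuron is assigned to a prototype by the sign of its mean
    specialization over the final quarter of the run. Its accuracy is the
    fraction of presentations of its group (prototype plus distance-1
    patterns; ambiguous patterns excluded) in the window on which it won.
    ``None`` when the window contains no presentations of the group.
    """
    part = _window_slice(records, window, end)
    assignment = _assignments(records)
    accuracy = {}
    for i, proto in assignment.items():
        mask = part["group"].isin([f"proto_{proto}", f"delta_{proto}"])
        n = int(mask.sum())
        if n == 0:
            accuracy[i] = None
        else:
            accuracy[i] = float((part.loc[mask, "winner"] == i).mean())
    return {"assignment": assignment, "accuracy": accuracy}


def weight_noise_estimate(trace) -> tuple[float, float]:
    """(overall weight change, noise s.d.) of one weight trace.

    Fits the trace with a saturating exponential; the overall change is
    fit(end) - fit(start) and the noise estimate is the s.d. of the fit
    residual.
    """
    x = np.asarray(trace, dtype=float)
    fit = fit_saturating_exponential(x)
    change = float(fit.predict(x.size - 1) - fit.predict(0))
    return change, fit.residual_sd
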