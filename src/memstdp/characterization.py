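"""Block-protocol characterization of a memristive synapse.

Reproduces the standard bench protocol for extracting a device's conductance
operating range: four blocks of identical STDP events (LTD-only, LTP,
LTD-again, pre-only; 2,400 events each by default) are applied while the
conductance is logged after every event. The saturating tails of the LTP and
LTD blocks are fitted with ``g(t) = offset + amplitude * exp(-rate * t)``;
the constant terms of the two fits are the operational bounds
``(g_high, g_low)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

from .device import MemristorState, simulate_events

__all__ = [
    "BlockSpec",
    "ExpFit",
    "FitError",
    "RangeError",
    "BLOCK_EVENT_MAP",
    "default_protocol",
    "load_protocol",
    "run_characterization",
    "moving_average",
    "fit_saturating_exponential",
    "extract_operating_range",
    "write_trace",
    "read_trace",
]

# (PRE, POST) pair applied for every event of a block of the given kind.
BLOCK_EVENT_MAP = {
    "ltd_only": (0, 1),
    "ltp": (1, 1),
    "ltd_again": (0, 1),
    "pre_only": (1, 0),
}


class FitError(RuntimeError):
    """Raised when the saturating-exponential fit does not converge."""


class RangeError(ValueError):
    """Raised when the extracted operating range is degenerate."""


@dataclass(frozen=True)
class BlockSpec:
    """One characterization block: an event kind and a repetition count."""

    kind: str
    n_events: int = 2400

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_EVENT_MAP:
            raise ValueError(
                f"unknown block kind {self.kind!r}; expected one of "
                f"{sorted(BLOCK_EVENT_MAP)}"
            )
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def default_protocol(n_events: int = 2400) -> list[BlockSpec]:
    """LTD-only, LTP, LTD-again, pre-only -- the standard four-block order."""
    return [
        BlockSpec("ltd_only", n_events),
        BlockSpec("ltp", n_events),
        BlockSpec("ltd_again", n_events),
        BlockSpec("pre_only", n_events),
    ]


def load_protocol(path) -> list[BlockSpec]:
    """Read a protocol file: a YAML list of ``{kind, n_events}`` mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [BlockSpec(b["kind"], int(b.get("n_events", 2400))) for b in raw]


def run_characterization(
    device: MemristorState,
    blocks: list[BlockSpec],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, MemristorState]:
    """Apply the block protocol, logging conductance after every event.

    Returns a frame with columns ``event_index, block, kind, conductance``
    and the final device state. An empty block list yields an empty trace.
    """
    frames = []
    state = device
    offset = 0
    for b_idx, block in enumerate(blocks):
        pre_bit, post_bit = BLOCK_EVENT_MAP[block.kind]
        pre = np.full(block.n_events, pre_bit, dtype=np.int64)
        post = np.full(block.n_events, post_bit, dtype=np.int64)
        trace, state = simulate_events(state, pre, post, rng)
        frames.append(
            pd.DataFrame(
                {
                    "event_index": np.arange(offset, offset + block.n_events),
                    "block": b_idx,
                    "kind": block.kind,
                    "conductance": trace,
                }
            )
        )
        offset += block.n_events
    if not frames:
        return (
            pd.DataFrame(
                columns=["event_index", "block", "kind", "conductance"]
            ),
            state,
        )
    return pd.concat(frames, ignore_index=True), state


def moving_average(trace, window: int = 10) -> np.ndarray:
    """Centered running mean with windows shrinking at the edges.

    The window at position ``i`` spans the samples within ``window // 2``
    positions of ``i``, clipped to the trace; even windows therefore behave
    like the next odd size so that the average stays centered. ``window = 1``
    is the identity and the output always has the input's length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    r = window // 2
    if r == 0:
        return x.copy()
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - r)
    hi = np.minimum(n, idx + r + 1)
    return (cs[hi] - cs[lo]) / (hi - lo)


@dataclass(frozen=True)
class ExpFit:
    """Saturating-exponential fit ``g(t) = offset + amplitude * exp(-rate*t)``."""

    amplitude: float
    rate: float
    offset: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + self.amplitude * np.exp(-self.rate * t)

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "rate": self.rate,
            "offset": self.offset,
            "residual_sd": self.residual_sd,
        }


def _model(t, amplitude, rate, offset):
    return offset + amplitude * np.exp(-rate * t)


def fit_saturating_exponential(trace) -> ExpFit:
    """Least-squares fit of ``offset + amplitude * exp(-rate * t)``.

    ``t`` is the sample index. Initialization: offset from the mean of the
    last decile, amplitude from the first sample minus that offset, rate
    ``5 / len(trace)`` -- robust for saturating traces. The residual s.d. is
    the plain s.d. of (trace - fit).
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples to fit")
    mean = float(np.mean(x))
    if np.ptp(x) < 1e-12 * max(1.0, abs(mean)):
        # constant trace: amplitude 0, offset at the level, no residual
        return ExpFit(0.0, 5.0 / n, mean, float(np.std(x)))
    t = np.arange(n, dtype=float)
    offset0 = float(np.mean(x[-max(1, n // 10):]))
    amp0 = float(x[0] - offset0)
    rate0 = 5.0 / n
    p0 = (amp0, rate0, offset0)
    try:
        popt, _ = curve_fit(_model, t, x, p0=p0, maxfev=20000)
    except Exception as exc:  # noqa: BLE001 - re-raise with diagnostics
        raise FitError(
            f"saturating-exponential fit failed (n={n}, p0={p0})"
        ) from exc
    resid = x - _model(t, *popt)
    return ExpFit(
        amplitude=float(popt[0]),
        rate=float(popt[1]),
        offset=float(popt[2]),
        residual_sd=float(np.std(resid)),
    )


def extract_operating_range(ltp_fit: ExpFit, ltd_fit: ExpFit) -> tuple[float, float]:
    """Operating bounds from the constant terms of the block fits.

    ``g_high`` is the LTP-block asymptote, ``g_low`` the LTD-block asymptote.
    Raises :class:`RangeError` when they do not satisfy ``g_low < g_high``
    (device unusable).
    """
    g_high = ltp_fit.offset
    g_low = ltd_fit.offset
    if not g_low < g_high:
        raise RangeError(
            f"degenerate operating range: LTD asymptote {g_low:.4g} >= "
            f"LTP asymptote {g_high:.4g}"
        )
    return g_low, g_high


def write_trace(path, trace) -> None:
    """Write a conductance trace as CSV with header ``event_index,conductance``."""
    x = np.asarray(trace, dtype=float)
    df = pd.DataFrame({"event_index": np.arange(x.size), "conductance": x})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_trace(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "conductance" not in df.columns:
        raise ValueError(f"{path}: expected a 'conductance' column")
    return df["conductance"].to_numpy(dtype=float)
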