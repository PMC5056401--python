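"""Phenomenological model of a multi-state memristive synapse.

The synapse stores its weight in the conductance ``g`` of a metal-oxide
resistive-switching device. Plasticity is modelled at the event level: each
event carries a binary ``(PRE, POST)`` pair. A post-spike alone depresses the
device (LTD), a coincident pre+post spike potentiates it (LTP), and a
pre-spike alone is plasticity-neutral. The relative conductance change per
event depends exponentially on the running conductance,

.. math::

    \\text{LTP:}\\quad \\Delta g / g = +a_{pot} e^{-b_{pot} g}, \\qquad
    \\text{LTD:}\\quad \\Delta g / g = -a_{dep} e^{+b_{dep} g},

which makes plasticity self-limiting: potentiation stalls at high ``g`` and
the absolute depression step vanishes toward low ``g``. Under a stochastic
event mixture with LTP probability ``p`` the drift balance

.. math::

    p\\, g^{+}(g^{*}) = (1 - p)\\, g^{-}(g^{*})

has a unique root, so the equilibrium conductance encodes the conditional
probability ``p(PRE | POST = 1)`` of the input stream. Cycle-to-cycle
switching variability is multiplicative on each step; read-out noise is
additive on the conductance and independent between reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DevicePlasticityParams",
    "MemristorState",
    "PlasticityEvent",
    "SolverError",
    "relative_ltp",
    "relative_ltd",
    "apply_event",
    "read_samples",
    "read_conductance",
    "equilibrium_conductance",
    "simulate_events",
    "simulate_event_stream",
]


class SolverError(RuntimeError):
    """Raised when the equilibrium root search cannot bracket a sign change."""


@dataclass(frozen=True)
class DevicePlasticityParams:
    """Device-specific plasticity parameters of one memristive synapse.

    Parameters
    ----------
    a_pot, b_pot
        Scale (dimensionless) and decay rate (1/conductance-unit) of the
        relative LTP change ``g+ = a_pot * exp(-b_pot * g)``.
    a_dep, b_dep
        Scale and growth rate of the relative LTD change
        ``g- = a_dep * exp(+b_dep * g)``.
    g_low, g_high
        Operational conductance bounds in normalized conductance units.
        Physical Siemens values are irrelevant to the dynamics; only the
        (bounds, curve-shape) combination matters after the linear
        conductance-to-weight map.
    sigma_cycle
        S.d. of the multiplicative cycle-to-cycle variability applied to each
        conductance step (dimensionless, clipped to +-5 sigma).
    sigma_read
        S.d. of the additive read noise (conductance units, clipped to
        +-5 sigma).
    hard_bounds
        If True (default) the conductance is clipped to [g_low, g_high] after
        every update, modelling the physical saturation of the device at its
        operating bounds. If False only a positivity floor of ``g_low/100``
        is enforced.
    """

    a_pot: float
    b_pot: float
    a_dep: float
    b_dep: float
    g_low: float = 0.2
    g_high: float = 1.0
    sigma_cycle: float = 0.2
    sigma_read: float = 0.06
    hard_bounds: bool = True

    def __post_init__(self) -> None:
        for name in ("a_pot", "b_pot", "a_dep", "b_dep"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.g_low < self.g_high:
            raise ValueError("need 0 < g_low < g_high")
        if self.sigma_cycle < 0 or self.sigma_read < 0:
            raise ValueError("noise s.d. must be non-negative")

    @property
    def floor(self) -> float:
        """Positivity floor applied after every update (g_low / 100)."""
        return self.g_low / 100.0

    @property
    def g_mid(self) -> float:
        return 0.5 * (self.g_low + self.g_high)

    @classmethod
    def calibrated(
        cls,
        step_scale: float = 0.05,
        g_low: float = 0.2,
        g_high: float = 1.0,
        weight_limit: float = 2.2,
        **kwargs,
    ) -> "DevicePlasticityParams":
        """Parameter set whose implied weight-dependence is exactly sigmoidal.

        Chooses ``b_pot = b_dep = 2 * weight_limit / (g_high - g_low) / 2`` so
        that ``(b_pot + b_dep) * (g_high - g_low)`` equals the full abstract
        weight span (4.4 by default), and scales ``a_pot``/``a_dep`` so both
        relative changes equal ``step_scale`` at the range midpoint. The
        LTP/LTD balance point then sits exactly at the midpoint, and under the
        linear map sending (g_low, g_high) to (-weight_limit, +weight_limit)
        the balance function of the device is exactly ``sigma(w)`` -- the same
        weight dependence used by the software synapse rule.
        """
        slope = 2.0 * weight_limit / (g_high - g_low)
        b = slope / 2.0
        g_mid = 0.5 * (g_low + g_high)
        return cls(
            a_pot=step_scale * math.exp(b * g_mid),
            b_pot=b,
            a_dep=step_scale * math.exp(-b * g_mid),
            b_dep=b,
            g_low=g_low,
            g_high=g_high,
            **kwargs,
        )

    @classmethod
    def default(cls) -> "DevicePlasticityParams":
        return cls.calibrated()

    def to_dict(self) -> dict:
        return {
            "a_pot": self.a_pot,
            "b_pot": self.b_pot,
            "a_dep": self.a_dep,
            "b_dep": self.b_dep,
            "g_low": self.g_low,
            "g_high": self.g_high,
            "sigma_cycle": self.sigma_cycle,
            "sigma_read": self.sigma_read,
            "hard_bounds": self.hard_bounds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DevicePlasticityParams":
        return cls(**d)


@dataclass(frozen=True)
class MemristorState:
    """Current conductance of one device plus its plasticity parameters."""

    g: float
    params: DevicePlasticityParams

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError("conductance must be strictly positive")


@dataclass(frozen=True)
class PlasticityEvent:
    """One STDP event: binary pre- and post-spike indicators."""

    pre: int
    post: int

    def __post_init__(self) -> None:
        if self.pre not in (0, 1) or self.post not in (0, 1):
            raise ValueError("pre and post must be binary (0/1)")


def relative_ltp(g, params: DevicePlasticityParams):
    """Relative LTP change ``g+ = a_pot * exp(-b_pot * g)``.

    Strictly positive and strictly decreasing in ``g`` (self-limiting
    potentiation). Accepts scalars or arrays; the domain is ``g >= 0``.
    """
    if np.any(np.asarray(g) < 0):
        raise ValueError("conductance must be non-negative")
    return params.a_pot * np.exp(-params.b_pot * np.asarray(g, dtype=float))


def relative_ltd(g, params: DevicePlasticityParams):
    """Relative LTD change ``g- = a_dep * exp(+b_dep * g)``.

    The absolute depression step ``g * g-(g)`` is increasing in ``g``, so
    depression becomes ineffective toward the bottom of the conductance
    scale. Domain ``g >= 0``.
    """
    if np.any(np.asarray(g) < 0):
        raise ValueError("conductance must be non-negative")
    return params.a_dep * np.exp(params.b_dep * np.asarray(g, dtype=float))


def _clip_g(g: float, params: DevicePlasticityParams) -> float:
    if params.hard_bounds:
        return min(max(g, params.g_low), params.g_high)
    return max(g, params.floor)


def apply_event(
    state: MemristorState, event: PlasticityEvent, rng: np.random.Generator
) -> MemristorState:
    """Apply one STDP event and return the new device state.

    The conductance step is
    ``dg = POST * [PRE * g * g+(g) - (1 - PRE) * g * g-(g)] * (1 + eps)``
    with ``eps ~ Normal(0, sigma_cycle)`` clipped to +-5 sigma. Events with
    ``POST = 0`` leave the state exactly unchanged.
    """
    if event.post == 0:
        return state
    p = state.params
    g = state.g
    if event.pre:
        dg = g * p.a_pot * math.exp(-p.b_pot * g)
    else:
        dg = -g * p.a_dep * math.exp(p.b_dep * g)
    if p.sigma_cycle > 0:
        eps = rng.normal(0.0, p.sigma_cycle)
        eps = max(-5.0 * p.sigma_cycle, min(5.0 * p.sigma_cycle, eps))
        dg *= 1.0 + eps
    return replace(state, g=_clip_g(g + dg, p))


def read_samples(
    state: MemristorState, rng: np.random.Generator, n_reads: int
) -> np.ndarray:
    """``n_reads`` independent noisy conductance read-outs."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    s = state.params.sigma_read
    if s == 0:
        return np.full(n_reads, state.g)
    noise = np.clip(rng.normal(0.0, s, size=n_reads), -5.0 * s, 5.0 * s)
    return state.g + noise


def read_conductance(
    state: MemristorState, rng: np.random.Generator, n_reads: int = 25
) -> float:
    """Mean of ``n_reads`` noisy read-outs (exact when ``sigma_read = 0``)."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if state.params.sigma_read == 0:
        return state.g
    return float(np.mean(read_samples(state, rng, n_reads)))


def equilibrium_conductance(params: DevicePlasticityParams, p_ltp: float) -> float:
    """Conductance at which expected drift vanishes under LTP probability ``p``.

    Solves ``p * g+(g) = (1 - p) * g-(g)`` by bracketed root search on
    ``(g_low/10, 10*g_high)``. The root is strictly increasing in ``p_ltp``.
    Raises :class:`SolverError` when the drift does not change sign in the
    bracket (e.g. symmetric parameters at p=0.5, whose balance point is g=0).
    """
    if not 0.0 < p_ltp < 1.0:
        raise ValueError("p_ltp must lie strictly between 0 and 1")

    def drift(g: float) -> float:
        # common factor g divided out; sign structure is unchanged
        return p_ltp * params.a_pot * math.exp(-params.b_pot * g) - (
            1.0 - p_ltp
        ) * params.a_dep * math.exp(params.b_dep * g)

    lo, hi = params.g_low / 10.0, 10.0 * params.g_high
    f_lo, f_hi = drift(lo), drift(hi)
    if f_lo * f_hi > 0:
        raise SolverError(
            f"no drift sign change in bracket ({lo:g}, {hi:g}): "
            f"drift(lo)={f_lo:.3e}, drift(hi)={f_hi:.3e}, p_ltp={p_ltp}"
        )
    return float(brentq(drift, lo, hi, xtol=1e-12, rtol=1e-12))


def simulate_events(
    state: MemristorState,
    pre: np.ndarray,
    post: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, MemristorState]:
    """Apply a whole (PRE, POST) event sequence; return the per-event trace.

    Equivalent to repeated :func:`apply_event` but avoids per-event object
    construction; one cycle-variability draw is consumed per event regardless
    of its type, so traces are reproducible given the rng stream.
    """
    pre = np.asarray(pre, dtype=np.int64)
    post = np.asarray(post, dtype=np.int64)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    p = state.params
    if p.sigma_cycle > 0:
        eps = np.clip(rng.standard_normal(n), -5.0, 5.0) * p.sigma_cycle
    else:
        eps = np.zeros(n)
    ap, bp, ad, bd = p.a_pot, p.b_pot, p.a_dep, p.b_dep
    bounded = p.hard_bounds
    g_lo, g_hi, floor = p.g_low, p.g_high, p.floor
    g = state.g
    out = np.empty(n)
    exp = math.exp
    for i in range(n):
        if post[i]:
            if pre[i]:
                dg = g * ap * exp(-bp * g)
            else:
                dg = -g * ad * exp(bd * g)
            g += dg * (1.0 + eps[i])
            if bounded:
                g = min(max(g, g_lo), g_hi)
            else:
                g = max(g, floor)
        out[i] = g
    return out, replace(state, g=g)


def simulate_event_stream(
    state: MemristorState,
    p_ltp: float,
    n_events: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, MemristorState]:
    """Drive the device with a Bernoulli(p_ltp) LTP/LTD mixture.

    Every event has ``POST = 1``; ``PRE`` is 1 (LTP) with probability
    ``p_ltp`` and 0 (LTD) otherwise.
    """
    if not 0.0 <= p_ltp <= 1.0:
        raise ValueError("p_ltp must lie in [0, 1]")
    pre = (rng.random(n_events) < p_ltp).astype(np.int64)
    post = np.ones(n_events, dtype=np.int64)
    return simulate_events(state, pre, post, rng)
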