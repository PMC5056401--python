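"""Conditional-probability encoding in a single memristive synapse.

Drives one device with blocks of stochastic LTP/LTD mixtures (LTP with
probability ``p_ltp`` per event, fixed within a block), records the converged
conductance per block from an averaged multi-read readout, and fits the line
of converged conductance versus LTP/LTD composition. Blocks run sequentially
on the same device state with no reset between blocks or runs, matching how
a device would be exercised on the bench.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .device import MemristorState, read_samples, simulate_event_stream

__all__ = [
    "EncodingRunSpec",
    "ConvergenceRecord",
    "ConvergenceLineFit",
    "DESCENDING_SCHEDULE",
    "run_block",
    "run_experiment",
    "fit_convergence_line",
    "run_encoding_protocol",
]

#: LTP probabilities 0.95, 0.85, ..., 0.05 (the monotone block schedule).
DESCENDING_SCHEDULE = tuple(round(0.95 - 0.1 * k, 2) for k in range(10))


@dataclass(frozen=True)
class EncodingRunSpec:
    """One run: an ordered LTP-probability schedule plus block sizing."""

    p_ltp_schedule: tuple
    events_per_block: int = 10_000
    readouts_per_block: int = 25
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.p_ltp_schedule) == 0:
            raise ValueError("schedule must contain at least one block")
        for p in self.p_ltp_schedule:
            if not 0.0 <= p <= 1.0:
                raise ValueError("every p_ltp must lie in [0, 1]")
        if self.events_per_block < 1:
            raise ValueError("events_per_block must be >= 1")
        if self.readouts_per_block < 1:
            raise ValueError("readouts_per_block must be >= 1")


@dataclass(frozen=True)
class ConvergenceRecord:
    """Converged conductance of one block: readout mean and s.d."""

    p_ltp: float
    g_final: float
    g_final_sd: float


@dataclass(frozen=True)
class ConvergenceLineFit:
    """OLS line of converged conductance on LTP probability."""

    slope: float
    intercept: float
    rmse: float

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "rmse": self.rmse}


def run_block(
    device: MemristorState,
    p_ltp: float,
    n_events: int,
    rng: np.random.Generator,
    readouts: int = 25,
) -> tuple[np.ndarray, ConvergenceRecord, MemristorState]:
    """One block of Bernoulli(p_ltp) LTP/LTD events plus a final readout.

    Returns the per-event conductance trace, the convergence record (mean and
    s.d. of ``readouts`` noisy reads taken after the last event), and the
    advanced device state.
    """
    trace, state = simulate_event_stream(device, p_ltp, n_events, rng)
    reads = read_samples(state, rng, readouts)
    record = ConvergenceRecord(
        p_ltp=float(p_ltp),
        g_final=float(np.mean(reads)),
        g_final_sd=float(np.std(reads, ddof=1)) if readouts > 1 else 0.0,
    )
    return trace, record, state


def run_experiment(
    spec: EncodingRunSpec,
    device: MemristorState,
    rng: np.random.Generator | None = None,
) -> tuple[list[ConvergenceRecord], MemristorState]:
    """Execute one run: all blocks sequentially on the same device state."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    records = []
    state = device
    for p in spec.p_ltp_schedule:
        _, record, state = run_block(
            state, p, spec.events_per_block, rng, spec.readouts_per_block
        )
        records.append(record)
    return records, state


def fit_convergence_line(records: list[ConvergenceRecord]) -> ConvergenceLineFit:
    """OLS of converged conductance on LTP probability.

    Records sharing a composition are averaged before the regression (one
    pooled point per composition); the RMSE is computed on the pooled points.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 convergence records to fit a line")
    pooled: dict[float, list[float]] = {}
    for r in records:
        pooled.setdefault(r.p_ltp, []).append(r.g_final)
    ps = np.array(sorted(pooled))
    gs = np.array([np.mean(pooled[p]) for p in ps])
    if ps.size < 2:
        raise ValueError("need at least 2 distinct compositions")
    res = stats.linregress(ps, gs)
    resid = gs - (res.intercept + res.slope * ps)
    return ConvergenceLineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def run_encoding_protocol(
    device: MemristorState,
    n_runs: int = 4,
    burn_in_runs: int = 1,
    events_per_block: int = 10_000,
    readouts_per_block: int = 25,
    scrambled_runs: tuple = (0, 2),
    seed: int = 0,
) -> dict:
    """Full multi-run protocol on one device, no reset between runs.

    Runs listed in ``scrambled_runs`` use a random permutation of the
    descending schedule; the others use it in order. The first
    ``burn_in_runs`` runs are excluded from the pooled line fit (a fresh
    device drifts into its operating range during them).

    Returns a dict with a tidy ``records`` frame (run, block, p_ltp, g_final,
    g_final_sd), the pooled :class:`ConvergenceLineFit` over post-burn-in
    runs, and the final device state.
    """
    rng = np.random.default_rng(seed)
    rows = []
    kept: list[ConvergenceRecord] = []
    state = device
    for run in range(n_runs):
        schedule = list(DESCENDING_SCHEDULE)
        if run in scrambled_runs:
            schedule = [schedule[i] for i in rng.permutation(len(schedule))]
        spec = EncodingRunSpec(
            tuple(schedule), events_per_block, readouts_per_block
        )
        records, state = run_experiment(spec, state, rng)
        for block, rec in enumerate(records):
            rows.append(
                {
                    "run": run,
                    "block": block,
                    "p_ltp": rec.p_ltp,
                    "g_final": rec.g_final,
                    "g_final_sd": rec.g_final_sd,
                }
            )
        if run >= burn_in_runs:
            kept.extend(records)
    fit = fit_convergence_line(kept) if len(kept) >= 3 else None
    return {
        "records": pd.DataFrame(rows),
        "fit": fit,
        "final_state": state,
    }
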