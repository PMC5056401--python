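# Methods

## Device model

A memristive synapse is reduced to a scalar conductance `g` plus a
parameter set. Plasticity is event-level: the simulator never models
voltages, pulse shapes or switching thresholds — an event is a binary
`(PRE, POST)` pair and its effect is

```
Δg = POST · [ PRE · g·g⁺(g) − (1−PRE) · g·g⁻(g) ] · (1 + ε),
g⁺(g) = a_pot e^(−b_pot g),   g⁻(g) = a_dep e^(+b_dep g),
ε ~ Normal(0, σ_cycle) clipped to ±5σ.
```

`POST = 0` events are exactly neutral. The single-exponential forms are the
ones under which the log-ratio `log(g⁻/g⁺)` is linear in `g`, so the
LTP/LTD *balance function* `g⁻/(g⁺+g⁻)` is a logistic in `g` — which is
what lets a linear conductance-to-weight map turn the hardware rule into
the same `(PRE − σ(w))` form as the software rule (see below).

Assumptions worth being explicit about:

- **Operating bounds are hard.** Real devices saturate at their operating
  range; the exponential effectiveness curves describe behaviour inside
  it. After every update `g` is clipped to `[g_low, g_high]`
  (`hard_bounds=True`, the default). With bounds off, only a positivity
  floor of `g_low/100` is enforced; the floor prevents log/ratio
  pathologies, since a pure-LTD stream would otherwise drive `g → 0`.
- **Noise placement.** Cycle-to-cycle variability is multiplicative on the
  *step* (identical stimulus and state give variable jumps); read noise is
  additive on `g` and never mutates it.

### Default parameters

Conductance is normalized: `g_low = 0.2`, `g_high = 1.0` (physical Siemens
values are irrelevant to the dynamics; only bounds and curve shape matter
after the linear weight map). The default calibration
`DevicePlasticityParams.calibrated()` fixes, for weight limit `L = 2.2`:

| parameter | value | why |
|---|---|---|
| `b_pot = b_dep` | 2.75 | `(b_pot+b_dep)(g_high−g_low) = 2L = 4.4`, so the balance logistic has unit slope in weight units |
| `a_pot`, `a_dep` | `0.05·e^(±2.75·0.6)` | both relative changes equal 0.05 (the step scale) at the range midpoint, putting the balance point exactly at `g_mid` — hence balance `= σ(w)` exactly |
| `σ_cycle` | 0.2 | effective weight-step s.d. ≈ 0.033, slightly below the software synapse's `σ_sw = 0.04`, which is documented as slightly *worse* than hardware |
| `σ_read` | 0.06 | ≈ 0.33 abstract weight per read, slightly below the software `σ_meas = 0.4`, same reasoning |

With this calibration the drift-balance equilibrium is
`g*(p) = g_mid + logit(p)/(b_pot+b_dep)`; in weight units `w* = logit(p)`,
identical to the software rule's fixed point. Equilibria for
`p ∈ (0.1, 0.9)` lie inside the operating range; beyond that the device
pins at a bound.

`equilibrium_conductance` solves the drift balance by bracketed root search
on `(g_low/10, 10·g_high)` rather than the closed form, so it remains
correct for arbitrary (non-calibrated) parameter sets; a missing sign
change in the bracket raises with diagnostics.

## Characterization pipeline

Four blocks of identical events (LTD-only, LTP, LTD-again, pre-only; 2,400
each by default) with the conductance logged per event. Numerical choices:

- **Moving average** (display smoothing): centered window of radius
  `window // 2`, shrinking at the edges so trace length is preserved; even
  windows therefore behave like the next odd size. Window 1 is the
  identity.
- **Saturating-exponential fit** `offset + amplitude·e^(−rate·t)` by
  Levenberg–Marquardt, initialized at offset = last-decile mean,
  amplitude = first sample − offset, rate = 5/length; this is robust for
  saturating traces, whose tail dominates the offset. Constant traces are
  returned directly with amplitude 0. The residual s.d. is the plain s.d.
  of (trace − fit). Fits are performed on the raw trace by default (the
  smoothed trace is a display aid).
- **Operating range**: `g_high` is the LTP-block fit offset, `g_low` the
  (second) LTD-block offset; `g_low ≥ g_high` is an error (device
  unusable).

## Probability encoding

Blocks of Bernoulli(`p_ltp`) LTP/LTD mixtures run sequentially on the same
device with no reset between blocks or runs; each block ends with the mean
of 25 noisy reads. The convergence line is OLS of converged conductance on
`p_ltp`, with records sharing a composition averaged before the fit and
the RMSE computed on the pooled points. The standard protocol is four runs
of ten blocks (compositions 0.95 … 0.05), runs 1 and 3 scrambled, run 1
treated as burn-in and excluded from the fit (configurable; the simulator
itself has no forming transient, so burn-in defaults matter only for
protocol fidelity).

With the default step scale (0.05) a device converges within tens of
events, so 10⁴-event blocks are fully converged and block order is
irrelevant. The order-sensitivity property (scrambled schedules leaving
larger line-fit residuals than monotone ones) is therefore exercised with
a slow-device parameterization (`step_scale = 2e-4`), which reproduces the
non-converged regime where each block's starting point matters.

## WTA network

Two neurons, four inputs, one synapse bank per neuron (all-hardware or
all-software). Per event:

1. fresh measurement/read noise per synapse → measured weights `v`;
2. `U_i = v_i·y + θ_i`; win probabilities by stable softmax (temperature
   1 — the normalized exponential is the standard probabilistic-WTA
   abstraction of lateral inhibition);
3. exactly one winner sampled; its synapses receive `(PRE=y_j, POST=1)`
   (losers receive nothing, which is exactly neutral);
4. both neurons update `θ_i ← θ_i + η_θ(1/2 − fired)` — the rate target is
   1/n_neurons, so θ drift vanishes when each neuron fires half the time.

Software updates use the *true* underlying `w` in `σ(w)` (measurement
noise corrupts decisions, not plasticity; switching variability `σ_sw`
plays the latter role). A switch (`plasticity_on_measured`) evaluates
`σ(·)` at the measured value instead. Software weights are clipped to
`[−2.2, 2.2]`, mirroring the hardware range, so the banks stay comparable.

Learning runs initialize software weights at 0, device conductances at the
map midpoint (mapped weight exactly 0; a real bench would pulse the device
toward mid-range by hand), and `θ = 0`. Reversal runs carry hardware state
and excitabilities over unchanged and re-initialize the software bank at
the extremes `±2.2` of the prototype the hardware neuron had claimed,
which flips the mapping and drives the memristors to re-specialize.

## Metrics

- **Specialization** `S_i = p_i(1001) − p_i(0110)`, with the win
  probabilities computed from noiseless underlying weights and current
  excitabilities: it describes intrinsic preference, not a particular
  noisy read. For two neurons `S_0 = −S_1` exactly.
- **Pattern groups** by Hamming distance to the prototypes: distance 0 →
  prototype group, distance 1 → delta group, the six distance-2 patterns
  are equidistant from both prototypes and labelled ambiguous.
- **Classification accuracy**: each neuron is assigned a prototype by the
  sign of its mean specialization over the final quarter of the run; its
  accuracy over a window (41 events by default, clamped to the run length)
  is its win fraction on its group's presentations, ambiguous patterns
  excluded (undefined — reported as null — if the window holds none).
- **Weight-trace noise**: each weight trace is fitted with the saturating
  exponential; overall change = fit(end) − fit(start), noise = residual
  s.d.

## What the generator does and does not emulate

Synthetic inputs are exactly the study conditions: equiprobable prototypes
`0110`/`1001`, independent 10% bit flips, 1,200 events per run. The
simulator reproduces event-level statistics and noise *placement*, not
device physics: no forming transients, no retention/endurance drift, no
threshold-voltage variability, no device-to-device spread (all four
hardware synapses share one parameter set). Passing tests therefore show
that the learning architecture is robust to state-dependent, noisy,
bounded plasticity of the modelled magnitudes — not that any particular
physical device realizes those magnitudes.

## Problem sizes used in tests and the acceptance script

Multi-seed claims use 20–21 seeds (learning accuracy, reversal sign
flips); equilibrium/oracle checks use 10⁵-event streams with small step
scales; pattern statistics use 10⁵ samples. These sizes put Monte-Carlo
error comfortably below the asserted tolerances while keeping a full run
of the suite in the tens of seconds.

## Known limitations

- The softmax WTA and the specialization metric are two-neuron in the
  provided protocols; the primitives accept any neuron count, but nothing
  beyond 2×4 is exercised.
- Reported accuracy saturates at 1.0 only in the majority of seeds: with
  measurement noise `σ_meas = 0.4` the win probability on distance-1
  patterns is ≈0.97–0.99 per presentation, so a minority of runs drop one
  or two of the 41 final samples.
- The equilibrium analysis ignores the hard bounds; for compositions whose
  balance point lies outside `(g_low, g_high)` the device pins at a bound
  instead of the returned root.
- Device parameter defaults are a calibrated stand-in, not fits to a
  physical device; all of them are exposed in configuration.
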