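# Methods

`psdlearn` implements precise-spike-driven (PSD) supervised synaptic
plasticity: a single spiking neuron is trained so that an input
spatiotemporal spike pattern evokes a prescribed output spike train
(hetero-association). This note documents the model, the calibrated
parameters, the synthetic study conditions, and the numerical and design
choices, in the order a reader would meet them.

## Neuron models

**Leaky integrate-and-fire (LIF).** The membrane potential obeys

    tau_m du/dt = -(u - V_rest) + R_m (I_syn(t) + I_b(t)),

with threshold `theta`, reset to `V_reset`, and an absolute refractory
period `t_ref` during which `u` is clamped at the reset value. Units are
normalized: `V_rest = V_reset = 0`, `theta = 1`, `R_m = 1`. Any rescaling
that preserves the threshold/reset/resistance relationships yields identical
spike trains, so these normalized values lose no generality. Defaults:
`tau_m = 10 ms`, `t_ref = 5 ms`.

**Izhikevich (IM), regular spiking.** The two-variable quadratic model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I,    du/dt = a (b v - u),

with spike cut-off at `v_peak = 30 mV` and reset `v <- c`, `u <- u + d`;
the standard regular-spiking constants `a = 0.02, b = 0.2, c = -65, d = 8`
are the default. Because this model lives in mV/ms units while the synaptic
current is kept on the normalized LIF scale, an `input_gain` (default 15)
maps one scale into the other. The gain was calibrated once so that the
initial-weight distribution that makes the LIF neuron fire a handful of
spikes per window does the same for the IM neuron; a characterization test
asserts regular spiking (ISI coefficient of variation < 0.05) under
sustained near-constant drive.

## Synaptic current and kernel

Each afferent spike contributes a postsynaptic current (PSC) shaped by the
normalized double-exponential kernel

    K(s) = V0 (exp(-s / tau_s) - exp(-s / tau_f)),  s >= 0,

with `tau_s / tau_f = 4` fixed and `V0` chosen analytically so that
`max K = 1` (peak at `s* = tau_s tau_f / (tau_s - tau_f) ln(tau_s/tau_f)`).
The un-weighted PSC of afferent `i`, `I_i(t) = sum_f K(t - t_i^f)`, doubles
as the eligibility trace of the learning rule. The total synaptic current is
`I_syn(t) = sum_i w_i I_i(t)`.

**Kernel time constant.** The default is `tau_s = 10 ms` (`tau_f = 2.5 ms`).
This value was calibrated on the memory-capacity task: the causal window of
the kernel must be wide enough, relative to the output-timing tolerance
implied by the correctness criterion (below), that enough afferents can
cooperate on each desired spike. With `tau_s = 5 ms` the maximum load factor
of a 500-synapse neuron saturates near 0.08; with `tau_s = 10 ms` it reaches
the 0.13–0.14 range while every other experiment (association speed,
robustness, classification, OCR) retains its qualitative behaviour. The
constant is configurable everywhere (`KernelParams.from_ratio`).

## The PSD rule

Writing the desired and actual output trains as Dirac combs `s_d`, `s_o`,
the rule is the Widrow-Hoff delta rule with the eligibility trace standing
in for the input:

    dw_i/dt = eta [s_d(t) - s_o(t)] I_i(t).

A desired spike the neuron missed potentiates every afferent in proportion
to its instantaneous eligibility (LTP); an output spike at a non-desired
time depresses it (LTD); an output spike exactly at a desired time produces
no net change. Two schedules are provided:

* **trial** (default): the rule is integrated over the presentation,
  `dw_i = eta [ sum_{t_d} I_i(t_d) - sum_{t_o} I_i(t_o) ]`, applied once at
  trial end. All experiment drivers use this schedule.
* **online**: the signed update is applied at each desired/actual spike
  event during the simulation, so the membrane equation sees the evolving
  weights within the trial. Implemented for the LIF neuron; coincident
  desired and actual events in the same time step are netted before
  applying, so a perfect hit changes nothing. A desired spike inside the
  first integration step of the window cannot be matched by an output spike
  and is processed with the first step.

Weights are capped above at `w_max = 0.5 theta` so that no single synapse
can fire the neuron alone; there is no lower cap — efficacies may turn
negative (inhibitory), which the depression term produces naturally.

**Learning rate.** Default `eta = 0.02`. The parameter sweep driver shows
the familiar picture: at the default kernel time constant a wide band of
`eta` learns fast, while values above roughly 0.1 slow or destabilize
learning.

**Initial weights.** Drawn from a normal distribution clipped to
`[0, w_max]`, with mean set by a quasi-steady-drive argument: for a
single-spike pattern over `N` afferents in a window `T`, the mean input
current is `w_mean (N / T) * area(K)`, so `w_mean = drive * theta * T /
(R_m N area(K))` with `drive = 1.25` and relative sd 25%. This leaves the
untrained neuron firing a handful of spikes per window — different from the
target but not silent, the state the rule needs to start from.

## Spike-train distance and correctness

Distance is the van Rossum metric with the PSC kernel as filter, in squared
integral form:

    D = (1/tau) ∫ (f - g)^2 dt,

`f, g` being the two trains convolved with `K`, `tau = 10 ms`. Because both
filtered signals are sums of exponentials, the integral reduces to a closed
form over spike pairs; the default evaluation is exact and O(n_a n_b), and a
gridded numerical integration path (`method="grid"`, step 0.1 ms, domain
extended 10 tau_s past the window) exists for cross-checking. `sqrt(D)` is a
proper metric; thresholds are applied to `D` itself: **0.2** for
single-spike targets and **0.5** for multi-spike targets, strict inequality.
At the defaults, a single missing spike against a one-spike target gives
D ≈ 1.0, and a lone output spike passes the 0.2 level only within about
±1 ms of its target, so "correct" means near-exact timing.

## Simulation numerics

Integration is grid-based with `dt = 0.1 ms` (well below `tau_f`, `t_ref`
and `tau_m`). The synaptic current is propagated *exactly* between grid
points by two exponential accumulators (one per kernel time constant), so
the only discretization error is in threshold-crossing detection: crossings
are detected at the end of a step and the spike time recorded at that grid
point, without interpolation. A refinement test checks that halving `dt`
moves LIF spike times by less than one coarse step. The LIF membrane uses
exponential Euler; the IM voltage uses two half-steps of forward Euler per
`dt` (the standard stabilization for the quadratic term). Background current
noise is Gaussian per step with standard deviation `current_sd / sqrt(dt)`,
making the integrated noise variance independent of the step size.

Spikes are represented as real-valued times; the grid is a simulation device
only. Spike-to-bin assignment uses half-open bins `[k dt, (k+1) dt)` with
the final bin closed, so a spike exactly at the window boundary is kept.

## Synthetic study conditions

The generators define the study conditions; their defaults are the
experiment protocol, not tuning knobs:

* **patterns**: `N = 500` afferents, window `T = 200 ms`, one spike per
  afferent uniform on the window (`single_uniform`); the multi-spike variant
  draws homogeneous Poisson trains with per-afferent rates uniform in
  10–40 Hz, giving the 2–8 spikes per afferent of the multi-spike regime.
* **targets**: four spikes evenly spread over the window,
  `T/5 {1,2,3,4} = 40/80/120/160 ms`; category tasks use one desired spike
  per category at those same times.
* **stimulus noise**: Gaussian jitter of each spike time, reflected at the
  window boundaries (preserves spike counts and, for interior spikes, the
  marginal sd). Default training noise level 2 ms.
* **background noise**: the current noise above; default training strength
  0.2 in normalized current units.
* **digits**: ten 20x20 black/white bitmaps upscaled from a 5x7 block font —
  synthetic stand-ins for scanned digit images (the pipeline consumes only
  binary bitmaps). Reversal noise flips each pixel independently with the
  stated probability.

What the generators do *not* emulate: correlated afferents, rate-coded
inputs, trial-to-trial latency drift, or realistic digit glyph variability.
Passing tests therefore demonstrate the learning rule's behaviour under its
stated idealized conditions, not performance on recorded neural data or real
OCR corpora.

## Experiments

* **Association** (`run_association`): one pattern, 4-spike target; the
  distance trajectory typically reaches the 0.2 level in well under ten
  epochs (median ≈ 7 over seeds). `run_retarget` switches the target after
  convergence and re-trains; `run_generality` trains LIF and IM neurons on
  identical inputs/targets/initial weights (convergence level 0.5 — the IM
  model's intrinsic dynamics bound its timing precision more loosely).
* **Robustness** (`run_robustness`): 10 templates (5 at desk scale in the
  acceptance suite), 400 training epochs, 20 test patterns per template per
  noise level, correctness at 0.5. Noisy training presents freshly jittered
  copies (or injects current noise) every epoch; it sacrifices zero training
  error for markedly better generalization at and below the training level.
* **Capacity** (`run_capacity`): loads alpha = P/N on a grid of step 0.008,
  P single-spike patterns assigned evenly to 4 categories, one desired spike
  per category, budget 500 epochs, correctness at 0.2. `alpha_max` is the
  largest tested load at which at least half the runs memorize everything.
  `alpha_eff` is the largest load whose mean epochs-to-success is at most
  100, where the mean counts failed runs at the budget — the mean-epoch
  curve is what rises sharply toward the failure ceiling at the capacity
  limit, and averaging only successful runs would let a lucky survivor above
  capacity dominate at small run counts. Default 10 runs per load (a
  desk-scale choice; the `--runs` flag raises it).
* **Parameter sweep** (`run_sweep`): mean epochs to memorize 10 patterns
  over an `eta x tau_s` grid, failures counted at the budget.
* **Classification** (`run_classification`): 3 fixed random templates,
  jitter sd 2 ms, 20 training and 40 test instances per category, one neuron
  per category trained (100 epochs) to fire the common 4-spike target for
  its own category and stay silent otherwise. Decisions: *absolute
  confidence* (own neuron's distance below 0.5) or *relative confidence*
  (arg-min of distance across neurons, ties to the lowest index). Relative
  confidence consistently dominates: it only needs the right neuron to be
  *closest*, not close.
* **OCR** (`run_ocr`): ten neurons, one per digit, phase-encoded 400-pixel
  bitmaps, 40 training epochs; each epoch presents per digit the clean
  template plus 9 freshly drawn noisy copies at reversal noise 0.05.
  Testing sweeps the noise level with relative-confidence decisions and
  tracks one digit's own-neuron distance as a direct association measure.

All drivers are deterministic given a master seed: every random stream is a
labelled child of a single `RngSpec`, so reruns are bit-for-bit identical.

## Phase encoder

Each pixel owns an encoding unit with a subthreshold oscillation
`A cos(omega t + phi_i)`, `phi_i = phi0 + i * dphi`, `dphi = 2 pi / n`
(`n` = pixel count), period 200 ms so one cycle fills the learning window.
A white pixel shifts the unit's potential up by `shift = 0.6`, black shifts
it down; a positive threshold catches the shifted-up peak, a negative
threshold the shifted-down trough. The thresholds sit below `A + shift` by
`A (1 - cos(omega dt))` — exactly the sub-peak dip of one sampling step —
so the mechanistic simulation is guaranteed to catch one crossing per
period within one `dt` of the extremum. Consequently a unit emits exactly
one spike per period, at the peak phase for white and the phase shifted by
180 degrees for black, and flipping a pixel moves that unit's spike by
exactly half a period. The closed-form spike times are the default; the
mechanistic positive/negative/output-neuron simulation is kept as the
independent oracle, and the two agree within one grid step (circularly, for
peaks adjacent to the window boundary).

## Known limitations

* Single neurons only; no layers, conduction delays, or lateral
  interaction beyond the decision rule.
* The capacity and efficient-load estimates at 10 runs per load carry a
  grid-step (0.008) plus sampling uncertainty of roughly one to two grid
  steps.
* Online updating is LIF-only.
* The IM model's spike times are controlled less precisely than the LIF's;
  the generality protocol therefore uses the 0.5 correctness level.
* Alternative PSC kernels (single exponential, alpha) are an interface hook
  (`KernelParams` is the only kernel consumer) but not implemented.
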