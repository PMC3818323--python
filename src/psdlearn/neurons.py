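"""Forward simulation of the postsynaptic neuron.

Two point-neuron models are provided, both driven by the same weighted sum of
double-exponential postsynaptic currents plus optional Gaussian background
current noise:

* leaky integrate-and-fire (LIF): ``tau_m du/dt = -(u - V_rest) + R_m (I_syn + I_b)``
  with threshold/reset and an absolute refractory period.  Units are
  normalized: ``V_rest = V_reset = 0`` and threshold ``theta = 1`` by default
  (any rescaling that keeps the threshold/reset/resistance relationships is
  equivalent).
* Izhikevich regular-spiking (IM): two-variable quadratic model
  ``dv/dt = 0.04 v^2 + 5 v + 140 - u + I``, ``du/dt = a (b v - u)`` with spike
  cut-off at ``v_peak`` and after-spike reset ``v <- c, u <- u + d``.  The
  synaptic current is scaled by ``input_gain`` to map the normalized LIF
  current scale into the model's mV/ms units.

Integration is grid-based (exponential Euler for the LIF membrane, two
half-steps for the Izhikevich voltage); the synaptic current itself is
propagated exactly between grid points via two exponential accumulators, so
refining ``dt`` only sharpens threshold-crossing times.  Threshold crossings
are detected at the end of each step and the spike time recorded at that grid
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelParams, psc_trace
from .spike_core import RngSpec, SpikePattern, SpikeTrain

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "LIFParams",
    "IMParams",
    "SynapticState",
    "NoiseSpec",
    "synaptic_current",
    "simulate_lif",
    "simulate_izhikevich",
]


@dataclass(frozen=True)
class LIFParams:
    """Normalized leaky integrate-and-fire parameters."""

    tau_m: float = 10.0    # membrane time constant, ms
    r_m: float = 1.0       # membrane resistance, normalized
    theta: float = 1.0     # firing threshold
    v_rest: float = 0.0
    v_reset: float = 0.0
    t_ref: float = 5.0     # absolute refractory period, ms

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.theta <= self.v_reset:
            raise ValueError("theta must exceed v_reset")


@dataclass(frozen=True)
class IMParams:
    """Izhikevich model constants; defaults are the standard regular-spiking set.

    ``input_gain`` converts the normalized synaptic-current scale shared with
    the LIF model into the quadratic model's units; it is calibrated once so
    that weights trained at the LIF scale also drive this neuron (see the
    characterization test).
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0
    input_gain: float = 15.0

    @property
    def v_rest(self) -> float:
        """Stable resting potential (lower root of the zero-input nullcline)."""
        # 0.04 v^2 + (5 - b) v + 140 = 0
        disc = (5.0 - self.b) ** 2 - 4 * 0.04 * 140.0
        return (-(5.0 - self.b) - np.sqrt(disc)) / (2 * 0.04)


@dataclass
class SynapticState:
    """Synaptic efficacies with a per-synapse upper cap."""

    weights: np.ndarray
    w_max: float = 0.5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).copy()
        if np.any(self.weights > self.w_max + 1e-12):
            raise ValueError("weights exceed w_max")

    def copy(self) -> "SynapticState":
        return SynapticState(self.weights.copy(), self.w_max)


@dataclass(frozen=True)
class NoiseSpec:
    """Background current noise: zero-mean Gaussian, strength = ``current_sd``.

    Per simulation step the injected current has standard deviation
    ``current_sd / sqrt(dt)`` so that the integrated noise variance is
    independent of the step size (diffusion scaling).
    """

    current_sd: float = 0.0
    rng: RngSpec = field(default_factory=lambda: RngSpec(0, "noise"))

    def __post_init__(self) -> None:
        if self.current_sd < 0:
            raise ValueError("current_sd must be non-negative")


def synaptic_current(pattern: SpikePattern, weights, params: KernelParams, t):
    """Weighted sum of per-afferent PSC traces at time(s) ``t`` (analytic)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != pattern.n_afferents:
        raise ValueError(
            f"{weights.shape[0]} weights for {pattern.n_afferents} afferents"
        )
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros(np.atleast_1d(t_arr).shape, dtype=float)
    for w, tr in zip(weights, pattern.trains):
        if w != 0.0 and len(tr):
            out += w * np.atleast_1d(psc_trace(tr, params, t_arr))
    return float(out[0]) if t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# fast grid machinery


def _n_steps(window: float, dt: float) -> int:
    return max(int(round(window / dt)), 1)


def binned_injections(pattern: SpikePattern, weights: np.ndarray,
                      kernel: KernelParams, dt: float, n_steps: int) -> np.ndarray:
    """Per-step weighted kernel injections: spikes land in bin floor(t/dt)."""
    idx, times = pattern.flat()
    if idx.size == 0:
        return np.zeros(n_steps)
    bins = np.minimum(np.floor(times / dt).astype(np.int64), n_steps - 1)
    return np.bincount(bins, weights=np.asarray(weights)[idx] * kernel.v0,
                       minlength=n_steps)


@njit(cache=True)
def _lif_loop(inj, noise, em, r_one_minus_em, ds, df, v_rest, v_reset, theta,
              ref_steps, u0):  # pragma: no cover - numba kernel
    n = inj.shape[0]
    u_trace = np.empty(n + 1)
    u_trace[0] = u0
    spikes = np.empty(n, dtype=np.int64)
    n_spk = 0
    a_s = 0.0
    a_f = 0.0
    u = u0
    ref_left = 0
    for k in range(n):
        a_s = a_s * ds + inj[k]
        a_f = a_f * df + inj[k]
        i_syn = a_s - a_f + noise[k]
        if ref_left > 0:
            ref_left -= 1
            u = v_reset
        else:
            u = v_rest + (u - v_rest) * em + r_one_minus_em * i_syn
            if u >= theta:
                spikes[n_spk] = k + 1
                n_spk += 1
                u = v_reset
                ref_left = ref_steps
        u_trace[k + 1] = u
    return u_trace, spikes[:n_spk]


@njit(cache=True)
def _izh_loop(inj, noise, a, b, c, d, v_peak, gain, ds, df, dt, v0,
              u0):  # pragma: no cover - numba kernel
    n = inj.shape[0]
    v_trace = np.empty(n + 1)
    v_trace[0] = v0
    spikes = np.empty(n, dtype=np.int64)
    n_spk = 0
    a_s = 0.0
    a_f = 0.0
    v = v0
    u = u0
    for k in range(n):
        a_s = a_s * ds + inj[k]
        a_f = a_f * df + inj[k]
        i_in = gain * (a_s - a_f + noise[k])
        # two half-steps on v for numerical stability of the quadratic term
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_in)
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_in)
        u += dt * a * (b * v - u)
        if v >= v_peak:
            spikes[n_spk] = k + 1
            n_spk += 1
            v = c
            u += d
        v_trace[k + 1] = v
    return v_trace, spikes[:n_spk]


def _noise_array(noise: NoiseSpec | None, n_steps: int, dt: float) -> np.ndarray:
    if noise is None or noise.current_sd == 0.0:
        return np.zeros(n_steps)
    gen = noise.rng.generator()
    return gen.normal(0.0, noise.current_sd / np.sqrt(dt), size=n_steps)


def simulate_lif(pattern: SpikePattern, syn: SynapticState, lif: LIFParams,
                 kernel: KernelParams, noise: NoiseSpec | None = None,
                 dt: float = 0.1, *, _noise_arr: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, SpikeTrain]:
    """Simulate the LIF neuron over the pattern window.

    Returns the membrane-potential trace on the grid (length ``n_steps + 1``)
    and the emitted spike train.  With zero noise the result is fully
    deterministic.
    """
    if dt > lif.tau_m / 10.0:
        raise ValueError(f"dt={dt} too coarse for tau_m={lif.tau_m} (need dt <= tau_m/10)")
    n_steps = _n_steps(pattern.window, dt)
    inj = binned_injections(pattern, syn.weights, kernel, dt, n_steps)
    noise_arr = _noise_arr if _noise_arr is not None else _noise_array(noise, n_steps, dt)
    em = np.exp(-dt / lif.tau_m)
    u_trace, spike_steps = _lif_loop(
        inj, noise_arr, em, lif.r_m * (1.0 - em),
        np.exp(-dt / kernel.tau_s), np.exp(-dt / kernel.tau_f),
        lif.v_rest, lif.v_reset, lif.theta,
        int(round(lif.t_ref / dt)), lif.v_rest,
    )
    if not np.all(np.isfinite(u_trace)):
        raise FloatingPointError("non-finite membrane potential in LIF simulation")
    times = np.minimum(spike_steps * dt, pattern.window)
    return u_trace, SpikeTrain(times, pattern.window)


def simulate_izhikevich(pattern: SpikePattern, syn: SynapticState, im: IMParams,
                        kernel: KernelParams, noise: NoiseSpec | None = None,
                        dt: float = 0.1) -> tuple[np.ndarray, SpikeTrain]:
    """Simulate the Izhikevich regular-spiking neuron over the pattern window."""
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms for the Izhikevich integrator")
    n_steps = _n_steps(pattern.window, dt)
    inj = binned_injections(pattern, syn.weights, kernel, dt, n_steps)
    noise_arr = _noise_array(noise, n_steps, dt)
    v_rest = im.v_rest
    v_trace, spike_steps = _izh_loop(
        inj, noise_arr, im.a, im.b, im.c, im.d, im.v_peak, im.input_gain,
        np.exp(-dt / kernel.tau_s), np.exp(-dt / kernel.tau_f), dt,
        v_rest, im.b * v_rest,
    )
    if not np.all(np.isfinite(v_trace)):
        raise FloatingPointError("non-finite membrane potential in Izhikevich simulation")
    times = np.minimum(spike_steps * dt, pattern.window)
    return v_trace, SpikeTrain(times, pattern.window)
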