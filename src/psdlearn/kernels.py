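"""Normalized double-exponential postsynaptic-current (PSC) kernel.

The kernel is

    K(s) = V0 * (exp(-s / tau_s) - exp(-s / tau_f)),   s >= 0;   K(s) = 0 otherwise,

with slow and fast decay constants ``tau_s > tau_f`` at a fixed ratio
(default 4) and ``V0`` chosen so the peak value of the kernel is exactly 1.
Convolving an afferent spike train with ``K`` gives the un-weighted
postsynaptic current of that afferent — the eligibility trace that both the
membrane equation and the plasticity rule consume.

Evaluation is analytic (exact exponentials at the query times); a gridded
convolution path used as a cross-check in the test-suite lives in the tests,
not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spike_core import SpikeTrain

__all__ = ["KernelParams", "normalization_factor", "kernel_value", "psc_trace",
           "kernel_peak_time"]

#: default slow/fast decay ratio tau_s / tau_f
DEFAULT_RATIO = 4.0
#: default slow decay constant, ms (calibrated; see the methods note)
DEFAULT_TAU_S = 10.0


def kernel_peak_time(tau_s: float, tau_f: float) -> float:
    """Time ``s*`` at which the (unnormalized) kernel is maximal.

    Solves d/ds [exp(-s/tau_s) - exp(-s/tau_f)] = 0:
    ``s* = tau_s*tau_f/(tau_s - tau_f) * ln(tau_s/tau_f)``.
    """
    return tau_s * tau_f / (tau_s - tau_f) * np.log(tau_s / tau_f)


def normalization_factor(tau_s: float, tau_f: float) -> float:
    """Factor ``V0`` making the kernel peak equal 1."""
    if not (tau_s > tau_f > 0):
        raise ValueError(f"need tau_s > tau_f > 0, got tau_s={tau_s}, tau_f={tau_f}")
    s_star = kernel_peak_time(tau_s, tau_f)
    return 1.0 / (np.exp(-s_star / tau_s) - np.exp(-s_star / tau_f))


@dataclass(frozen=True)
class KernelParams:
    """PSC kernel parameters: slow/fast decay constants and normalization.

    ``v0`` is always derived from the time constants; only ``tau_s`` and the
    ratio are free.  ``truncation_factor`` bounds the kernel support at
    ``truncation_factor * tau_s`` in the fast evaluation paths (the tail
    beyond 10 tau_s is below 2e-5 of the peak).
    """

    tau_s: float = DEFAULT_TAU_S
    tau_f: float = DEFAULT_TAU_S / DEFAULT_RATIO
    v0: float = field(init=False)
    truncation_factor: float = 10.0

    def __post_init__(self) -> None:
        if not (self.tau_s > self.tau_f > 0):
            raise ValueError(
                f"need tau_s > tau_f > 0, got tau_s={self.tau_s}, tau_f={self.tau_f}"
            )
        object.__setattr__(self, "v0", normalization_factor(self.tau_s, self.tau_f))

    @classmethod
    def from_ratio(cls, tau_s: float = DEFAULT_TAU_S, ratio: float = DEFAULT_RATIO,
                   truncation_factor: float = 10.0) -> "KernelParams":
        return cls(tau_s=tau_s, tau_f=tau_s / ratio, truncation_factor=truncation_factor)

    @property
    def peak_time(self) -> float:
        return kernel_peak_time(self.tau_s, self.tau_f)

    @property
    def support(self) -> float:
        """Truncated kernel support length in ms."""
        return self.truncation_factor * self.tau_s

    @property
    def area(self) -> float:
        """Integral of the kernel over its full support, ms."""
        return self.v0 * (self.tau_s - self.tau_f)


def kernel_value(s, params: KernelParams):
    """Kernel evaluated at lag ``s`` (ms); 0 for negative lags (causality)."""
    s = np.asarray(s, dtype=float)
    out = np.where(
        s >= 0,
        params.v0 * (np.exp(-np.maximum(s, 0.0) / params.tau_s)
                     - np.exp(-np.maximum(s, 0.0) / params.tau_f)),
        0.0,
    )
    return float(out) if out.ndim == 0 else out


def psc_trace(train: SpikeTrain, params: KernelParams, t) -> float | np.ndarray:
    """Un-weighted postsynaptic current of one afferent at time(s) ``t``.

    Sum of kernel responses to every spike at or before ``t``; this is the
    eligibility trace used by the plasticity rule.
    """
    t = np.asarray(t, dtype=float)
    if len(train) == 0:
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out
    lags = np.atleast_1d(t)[:, None] - train.times[None, :]
    out = kernel_value(lags, params).sum(axis=1)
    return float(out[0]) if t.ndim == 0 else out
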