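"""Phase encoding of black/white images into spatiotemporal spike patterns.

Each pixel owns an encoding unit riding a subthreshold membrane oscillation

    osc_i(t) = A * cos(omega * t + phi_i),    phi_i = phi0 + i * dphi (mod 2 pi),

with a fixed phase step ``dphi = 2 pi / n_units`` between neighbouring units.
A white pixel shifts the unit's potential up by ``shift``; a black pixel
shifts it down.  A positive neuron fires when the shifted potential crosses
``+threshold`` (possible only for white pixels, near the oscillation peak);
a negative neuron fires when it crosses ``-threshold`` (black pixels, near
the trough); either firing immediately triggers the unit's output neuron.
The thresholds sit a hair below ``A + shift`` so the single crossing per
period happens essentially at the peak/trough — so a unit emits exactly one
spike per period, at the peak phase for white and the phase shifted by 180
degrees for black.

The default ``encode_image`` uses the closed-form spike times implied by this
mechanism; ``encode_image_mechanistic`` actually simulates the oscillation
and threshold crossing on a grid and serves as the independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datagen import ImageSpec
from .spike_core import SpikePattern, SpikeTrain

__all__ = ["EncoderParams", "unit_phase", "encode_image",
           "encode_image_mechanistic"]


def _default_threshold(amplitude: float, period: float, dt: float = 0.1) -> float:
    """Threshold offset below the shifted peak sized to the sampling grid.

    The potential exceeds the threshold for phases within
    ``+- omega * dt`` of the peak, which guarantees the gridded mechanistic
    path catches the crossing and keeps its spike within one ``dt`` of the
    closed-form peak time.
    """
    omega_dt = 2.0 * np.pi * dt / period
    return amplitude * (1.0 - np.cos(omega_dt))


@dataclass(frozen=True)
class EncoderParams:
    """Oscillation and threshold parameters of the phase encoder."""

    n_units: int = 400
    period: float = 200.0       # ms; one oscillation fills the learning window
    amplitude: float = 1.0      # A, oscillation magnitude
    phi0: float = 0.0           # reference phase, rad
    dphi: float | None = None   # phase step between units; default 2 pi / n
    shift: float = 0.6          # pixel-driven potential offset
    thresholds: tuple[float, float] | None = None  # (positive, negative)
    dt: float = 0.1             # grid step of the mechanistic path, ms

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("need at least one encoding unit")
        if self.dphi is None:
            object.__setattr__(self, "dphi", 2.0 * np.pi / self.n_units)
        if abs(self.dphi * self.n_units - 2.0 * np.pi) > 1e-9:
            raise ValueError("dphi * n_units must equal 2 pi")
        if self.thresholds is None:
            delta = _default_threshold(self.amplitude, self.period, self.dt)
            peak = self.amplitude + self.shift
            object.__setattr__(self, "thresholds", (peak - delta, -(peak - delta)))

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period


def unit_phase(i: int, params: EncoderParams) -> float:
    """Intrinsic oscillation phase of unit ``i``: ``phi0 + i * dphi`` mod 2 pi."""
    if not 0 <= i <= params.n_units:
        raise IndexError(f"unit index {i} out of range for {params.n_units} units")
    return float(np.mod(params.phi0 + i * params.dphi, 2.0 * np.pi))


def _spike_times_closed_form(pixels_flat: np.ndarray,
                             params: EncoderParams) -> np.ndarray:
    i = np.arange(params.n_units)
    phi = np.mod(params.phi0 + i * params.dphi, 2.0 * np.pi)
    # white (0): spike at the oscillation peak, phase omega*t + phi = 0 (mod 2 pi)
    # black (1): trough, omega*t + phi = pi
    target = np.where(pixels_flat == 1, np.pi, 0.0)
    t = np.mod(target - phi, 2.0 * np.pi) / params.omega
    return np.mod(t, params.period)


def encode_image(img: ImageSpec, params: EncoderParams) -> SpikePattern:
    """Encode a bitmap: exactly one spike per pixel within one period."""
    flat = img.pixels.ravel()
    if flat.size != params.n_units:
        raise ValueError(f"{flat.size} pixels for {params.n_units} encoding units")
    times = _spike_times_closed_form(flat, params)
    return SpikePattern._unchecked(
        tuple(SpikeTrain._unchecked(np.array([t]), params.period) for t in times),
        params.period)


def encode_image_mechanistic(img: ImageSpec, params: EncoderParams) -> SpikePattern:
    """Grid simulation of the positive/negative/output neuron mechanism.

    For every unit the shifted oscillation is sampled at ``params.dt``; the
    positive neuron fires at the first upward crossing of the positive
    threshold, the negative neuron at the first downward crossing of the
    negative threshold, and the output neuron copies whichever fired.
    """
    flat = img.pixels.ravel()
    if flat.size != params.n_units:
        raise ValueError(f"{flat.size} pixels for {params.n_units} encoding units")
    thr_pos, thr_neg = params.thresholds
    t_grid = np.arange(0.0, params.period, params.dt)
    trains = []
    for i, px in enumerate(flat):
        phi = params.phi0 + i * params.dphi
        v = params.amplitude * np.cos(params.omega * t_grid + phi) \
            + (params.shift if px == 0 else -params.shift)
        hit = np.flatnonzero(v >= thr_pos) if px == 0 else np.flatnonzero(v <= thr_neg)
        if hit.size == 0:
            raise RuntimeError(
                f"unit {i}: no threshold crossing; encoder parameters inconsistent"
            )
        trains.append(SpikeTrain([t_grid[hit[0]]], params.period))
    return SpikePattern(trains, params.period)
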