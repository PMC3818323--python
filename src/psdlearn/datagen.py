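"""Synthetic stimulus generation.

Everything the experiments consume is generated here from seeded RNG streams:

* random spatiotemporal spike patterns — one uniform spike per afferent
  (``single_uniform``) or homogeneous Poisson trains with per-afferent rates
  drawn from a range (``poisson``);
* Gaussian-jittered copies of a pattern (stimulus noise);
* category template sets with jittered train/test instances;
* 20x20 black/white digit bitmaps with pixel-reversal noise for the OCR task.

All generators are bit-reproducible under a fixed :class:`~psdlearn.spike_core.RngSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spike_core import RngSpec, SpikePattern, SpikeTrain

__all__ = [
    "PatternSpec",
    "ImageSpec",
    "generate_pattern",
    "jitter_pattern",
    "make_category_set",
    "make_digit_images",
    "digit_templates",
]


@dataclass(frozen=True)
class PatternSpec:
    """Recipe for one random spatiotemporal pattern."""

    n_afferents: int = 500
    window: float = 200.0
    mode: str = "single_uniform"
    rate_range: tuple[float, float] = (10.0, 40.0)  # Hz, poisson mode
    rng: RngSpec = field(default_factory=lambda: RngSpec(0, "pattern"))

    def __post_init__(self) -> None:
        if self.n_afferents < 1:
            raise ValueError("need at least one afferent")
        if self.mode not in ("single_uniform", "poisson"):
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass(frozen=True)
class ImageSpec:
    """A black/white bitmap with a category label (1 = black, 0 = white)."""

    pixels: np.ndarray
    label: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if not np.isin(px, (0, 1)).all():
            raise ValueError("pixels must be strictly binary")
        px = px.astype(np.uint8)
        px.flags.writeable = False
        object.__setattr__(self, "pixels", px)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.size)


def generate_pattern(spec: PatternSpec,
                     gen: np.random.Generator | None = None) -> SpikePattern:
    """Draw one random pattern according to the spec."""
    gen = gen if gen is not None else spec.rng.generator()
    w = spec.window
    trains = []
    if spec.mode == "single_uniform":
        if w == 0.0:
            trains = [SpikeTrain([], 0.0) for _ in range(spec.n_afferents)]
        else:
            for t in gen.uniform(0.0, w, size=spec.n_afferents):
                trains.append(SpikeTrain._unchecked(np.array([t]), w))
    else:  # poisson
        lo, hi = spec.rate_range
        rates = gen.uniform(lo, hi, size=spec.n_afferents)
        for r in rates:
            n = gen.poisson(r * w / 1000.0)
            # resolve ties (probability ~0) by dropping duplicates
            ts = np.unique(gen.uniform(0.0, w, size=n))
            trains.append(SpikeTrain._unchecked(ts, w))
    return SpikePattern._unchecked(tuple(trains), w)


def _reflect(t: np.ndarray, window: float) -> np.ndarray:
    """Reflect times at 0 and window until all lie inside the interval."""
    if window == 0.0:
        return np.zeros_like(t)
    period = 2.0 * window
    t = np.mod(t, period)
    return np.where(t > window, period - t, t)


def jitter_pattern(pattern: SpikePattern, sigma: float,
                   rng: RngSpec | np.random.Generator) -> SpikePattern:
    """Perturb every spike by independent Normal(0, sigma) ms.

    Boundary handling reflects at 0 and the window so spike counts are
    preserved and the marginal jitter of interior spikes keeps sd ~ sigma.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return pattern
    gen = rng if isinstance(rng, np.random.Generator) else rng.generator()
    w = pattern.window
    trains = []
    for tr in pattern.trains:
        t = _reflect(tr.times + gen.normal(0.0, sigma, size=len(tr)), w)
        t = np.sort(t)
        # break exact ties introduced by reflection
        while t.size > 1 and np.any(np.diff(t) <= 0):
            dup = np.where(np.diff(t) <= 0)[0] + 1
            t[dup] = np.nextafter(t[dup - 1], np.inf)
            t = np.sort(t)
        trains.append(SpikeTrain._unchecked(t, w))
    return SpikePattern._unchecked(tuple(trains), w)


def make_category_set(n_categories: int, per_category: int, spec: PatternSpec,
                      sigma: float, rng: RngSpec
                      ) -> tuple[list[SpikePattern], list[tuple[SpikePattern, int]]]:
    """Fixed random templates plus jittered labelled instances.

    Returns ``(templates, instances)`` where ``instances`` is a list of
    ``(pattern, category_index)`` pairs, ``per_category`` instances each.
    """
    if n_categories < 1 or per_category < 1:
        raise ValueError("counts must be >= 1")
    gen = rng.generator()
    templates = [generate_pattern(spec, gen) for _ in range(n_categories)]
    instances = []
    for c, tpl in enumerate(templates):
        for _ in range(per_category):
            instances.append((jitter_pattern(tpl, sigma, gen), c))
    return templates, instances


# ---------------------------------------------------------------------------
# digit bitmaps

# 20x20 synthetic block-digit templates, drawn from a 5x7 seven-segment-style
# font upscaled to 20x20.  These stand in for the scanned digit images of a
# real OCR corpus; the encoding and learning pipeline only needs binary
# bitmaps plus reversal noise.
_FONT_5X7 = {
    "0": ["01110", "10001", "10011", "10101", "11001", "10001", "01110"],
    "1": ["00100", "01100", "00100", "00100", "00100", "00100", "01110"],
    "2": ["01110", "10001", "00001", "00010", "00100", "01000", "11111"],
    "3": ["11111", "00010", "00100", "00010", "00001", "10001", "01110"],
    "4": ["00010", "00110", "01010", "10010", "11111", "00010", "00010"],
    "5": ["11111", "10000", "11110", "00001", "00001", "10001", "01110"],
    "6": ["00110", "01000", "10000", "11110", "10001", "10001", "01110"],
    "7": ["11111", "00001", "00010", "00100", "01000", "01000", "01000"],
    "8": ["01110", "10001", "10001", "01110", "10001", "10001", "01110"],
    "9": ["01110", "10001", "10001", "01111", "00001", "00010", "01100"],
}


def digit_templates(size: int = 20) -> list[ImageSpec]:
    """Noise-free binary templates for digits 0-9 at ``size`` x ``size``."""
    out = []
    for digit in "0123456789":
        small = np.array([[int(ch) for ch in row] for row in _FONT_5X7[digit]],
                         dtype=np.uint8)
        rows = np.linspace(0, small.shape[0], size, endpoint=False).astype(int)
        cols = np.linspace(0, small.shape[1], size, endpoint=False).astype(int)
        big = small[np.ix_(rows, cols)]
        out.append(ImageSpec(big, digit))
    return out


def make_digit_images(noise_level: float, per_digit: int, rng: RngSpec,
                      size: int = 20) -> list[ImageSpec]:
    """Noisy digit bitmaps: each pixel flipped independently with the given probability."""
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError("noise_level must be in [0, 1]")
    gen = rng.generator()
    out = []
    for tpl in digit_templates(size):
        for _ in range(per_digit):
            flips = gen.random(tpl.pixels.shape) < noise_level
            out.append(ImageSpec(np.where(flips, 1 - tpl.pixels, tpl.pixels),
                                 tpl.label))
    return out
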