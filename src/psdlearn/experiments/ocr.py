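"""Optical character recognition with phase-encoded digit bitmaps.

Ten LIF neurons — one per digit — learn patterns produced by the phase
encoder from 20x20 black/white digit images.  Each neuron is trained to fire
the 4-spike target train for its own digit and to stay silent for the nine
others.  Every training epoch presents, per digit, the clean template plus
freshly drawn noisy copies (pixel-reversal noise).  Testing sweeps the
reversal-noise level; decisions use the relative-confidence criterion
(winning neuron = smallest distance to its own target), and the distance of
one tracked digit's own neuron to its target is recorded per level as a
direct measure of association quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datagen import digit_templates, make_digit_images
from ..encoding import EncoderParams, encode_image
from ..neurons import LIFParams
from ..psd import (PSDConfig, _CompiledPattern, _event_traces,
                   _simulate_compiled, _vr_distance_times, initial_weights)
from ..spike_core import RngSpec, SpikeTrain
from ._common import default_target

__all__ = ["OCRResult", "run_ocr"]


@dataclass
class OCRResult:
    test_levels: np.ndarray
    accuracy: np.ndarray            # relative-confidence accuracy per level
    tracked_digit: str
    tracked_distance: np.ndarray    # mean D(own neuron, target) per level


def run_ocr(train_noise: float = 0.05, per_digit_train: int = 10,
            epochs: int = 40,
            test_levels=(0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
            tests_per_digit: int = 10,
            encoder: EncoderParams | None = None,
            cfg: PSDConfig | None = None,
            lif: LIFParams | None = None,
            tracked_digit: str = "8",
            seed: int = 0) -> OCRResult:
    """Train the 10-neuron bank and evaluate accuracy across noise levels."""
    encoder = encoder or EncoderParams()
    cfg = cfg or PSDConfig()
    lif = lif or LIFParams()
    rng = RngSpec(seed, "ocr")
    gen = rng.generator()

    templates = digit_templates()
    n_digits = len(templates)
    window = encoder.period
    target = default_target(window)
    n_units = encoder.n_units
    kernel = cfg.kernel

    weights = np.stack([
        initial_weights(n_units, window, kernel, lif, cfg.w_max,
                        rng.child(f"w{k}")).weights
        for k in range(n_digits)
    ])

    # training: all ten neurons share each presentation
    for _epoch in range(epochs):
        images = list(templates)
        if per_digit_train > 1:
            images += make_digit_images(train_noise, per_digit_train - 1,
                                        rng.child(f"e{_epoch}"))
        order = gen.permutation(len(images))
        for ix in order:
            img = images[ix]
            label = int(img.label)
            pat = encode_image(img, encoder)
            cp = _CompiledPattern(pat, target, kernel, cfg.dt)
            noise_arr = np.zeros(cp.n_steps)
            for k in range(n_digits):
                out = _simulate_compiled(cp, weights[k], lif, kernel, cfg.dt,
                                         noise_arr)
                a_trace = _event_traces(cp.idx, cp.times, cp.n, out, kernel)
                d_trace = cp.d_trace if k == label else 0.0
                weights[k] = np.minimum(
                    weights[k] + cfg.eta * (d_trace - a_trace), cfg.w_max)

    # testing
    test_levels = np.asarray(test_levels, dtype=float)
    acc = np.empty_like(test_levels)
    tracked = np.empty_like(test_levels)
    for li, level in enumerate(test_levels):
        images = make_digit_images(level, tests_per_digit,
                                   rng.child(f"test{li}"))
        n_ok = 0
        tracked_d: list[float] = []
        for img in images:
            label = int(img.label)
            pat = encode_image(img, encoder)
            cp = _CompiledPattern(pat, target, kernel, cfg.dt)
            noise_arr = np.zeros(cp.n_steps)
            dists = np.empty(n_digits)
            for k in range(n_digits):
                out = _simulate_compiled(cp, weights[k], lif, kernel, cfg.dt,
                                         noise_arr)
                dists[k] = _vr_distance_times(out, target.times, kernel,
                                              cfg.tau_metric)
            n_ok += int(np.argmin(dists)) == label
            if img.label == tracked_digit:
                tracked_d.append(dists[int(tracked_digit)])
        acc[li] = n_ok / len(images)
        tracked[li] = float(np.mean(tracked_d))
    return OCRResult(test_levels, acc, tracked_digit, tracked)
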