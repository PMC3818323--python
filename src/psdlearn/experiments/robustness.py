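"""Robustness of the learned association against stimulus and background noise.

Protocol: fix a set of random single-spike template patterns, train one LIF
neuron to map every template onto the common 4-spike target train, then test
generalization on noisy copies of the templates (20 per template per noise
level).  An association counts as correct when the van Rossum distance to the
target is below 0.5.

Noise kinds:

* ``jitter`` — Gaussian jitter of each input spike time (sd in ms); in noisy
  training a freshly jittered copy of each template is presented every epoch;
* ``current`` — zero-mean Gaussian background current into the neuron
  (strength = sd of the integrated current per sqrt(ms)); in noisy training
  the noise also flows during training simulations.

Deterministic training presents the clean templates and converges to the
target exactly; noisy training cannot reach zero error but generalizes
better at and below its training noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datagen import PatternSpec, generate_pattern, jitter_pattern
from ..metrics import THRESHOLD_MULTI_SPIKE
from ..neurons import LIFParams, NoiseSpec
from ..psd import (PSDConfig, _CompiledPattern, _simulate_compiled,
                   _vr_distance_times, initial_weights, train_pattern_set)
from ..spike_core import RngSpec
from ._common import DEFAULT_N_AFFERENTS, DEFAULT_WINDOW, default_target

__all__ = ["RobustnessResult", "run_robustness"]


@dataclass
class RobustnessResult:
    noise_kind: str
    train_mode: str
    train_level: float
    test_levels: np.ndarray
    accuracy: np.ndarray          # mean over test patterns
    train_distance: list[float]   # per-epoch max distance during training


def run_robustness(noise_kind: str = "jitter", train_mode: str = "deterministic",
                   test_levels=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
                   train_level: float = 2.0,
                   n_templates: int = 10, tests_per_template: int = 20,
                   n_afferents: int = DEFAULT_N_AFFERENTS,
                   window: float = DEFAULT_WINDOW,
                   epochs: int = 400,
                   cfg: PSDConfig | None = None,
                   lif: LIFParams | None = None,
                   seed: int = 0,
                   threshold: float = THRESHOLD_MULTI_SPIKE) -> RobustnessResult:
    """Train under the chosen regime and measure accuracy per test noise level."""
    if noise_kind not in ("jitter", "current"):
        raise ValueError(f"unknown noise kind: {noise_kind!r}")
    if train_mode not in ("deterministic", "noisy"):
        raise ValueError(f"unknown train mode: {train_mode!r}")
    cfg = cfg or PSDConfig()
    cfg = PSDConfig(eta=cfg.eta, kernel=cfg.kernel, w_max=cfg.w_max,
                    max_epochs=epochs, convergence_distance=1e-12,
                    update_mode=cfg.update_mode, tau_metric=cfg.tau_metric,
                    dt=cfg.dt)
    lif = lif or LIFParams()
    rng = RngSpec(seed, f"robust-{noise_kind}-{train_mode}")
    gen = rng.generator()

    spec = PatternSpec(n_afferents=n_afferents, window=window,
                       mode="single_uniform")
    templates = [generate_pattern(spec, gen) for _ in range(n_templates)]
    target = default_target(window)
    desired = [target] * n_templates
    syn = initial_weights(n_afferents, window, cfg.kernel, lif, cfg.w_max,
                          rng.child("w"))

    per_epoch = None
    train_noise = None
    if train_mode == "noisy":
        if noise_kind == "jitter":
            def per_epoch(epoch, g):
                return [jitter_pattern(t, train_level, g) for t in templates]
        else:
            train_noise = NoiseSpec(current_sd=train_level, rng=rng.child("bg"))

    rec = train_pattern_set(templates, desired, syn, lif, cfg,
                            rng.child("train"), noise=train_noise,
                            per_epoch_patterns=per_epoch)

    # testing
    weights = rec.weights_final
    test_levels = np.asarray(test_levels, dtype=float)
    acc = np.empty_like(test_levels)
    tgen = rng.child("test").generator()
    compiled = {id(t): _CompiledPattern(t, target, cfg.kernel, cfg.dt)
                for t in templates}
    for li, level in enumerate(test_levels):
        n_ok = 0
        n_tot = 0
        for tpl in templates:
            for _ in range(tests_per_template):
                if noise_kind == "jitter":
                    pat = jitter_pattern(tpl, level, tgen)
                    cp = _CompiledPattern(pat, target, cfg.kernel, cfg.dt)
                    noise_arr = np.zeros(cp.n_steps)
                else:
                    cp = compiled[id(tpl)]
                    noise_arr = (tgen.normal(0.0, level / np.sqrt(cfg.dt),
                                             size=cp.n_steps)
                                 if level > 0 else np.zeros(cp.n_steps))
                out = _simulate_compiled(cp, weights, lif, cfg.kernel, cfg.dt,
                                         noise_arr)
                d = _vr_distance_times(out, target.times, cfg.kernel,
                                       cfg.tau_metric)
                n_ok += d < threshold
                n_tot += 1
        acc[li] = n_ok / n_tot
    return RobustnessResult(noise_kind, train_mode, train_level, test_levels,
                            acc, rec.distance_per_epoch)
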