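"""Classification of jittered spatiotemporal patterns; two decision criteria.

Setup: ``n_categories`` random template patterns are fixed; jittered copies
form the training and test sets.  One neuron per category is trained to fire
the common target train for patterns of its own category and to stay silent
for the others.

Decision criteria applied to the per-neuron output trains of a test pattern:

* absolute confidence — the pattern is correct iff the distance between its
  own category neuron's output and that neuron's target is below a threshold
  (0.5);
* relative confidence — the winning neuron is the one whose output is
  closest to its own desired train (arg-min of the distance; ties go to the
  lowest neuron index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..datagen import PatternSpec, make_category_set
from ..metrics import MetricParams, THRESHOLD_MULTI_SPIKE, van_rossum_distance
from ..neurons import LIFParams
from ..psd import PSDConfig, initial_weights, train_pattern_set
from ..spike_core import RngSpec, SpikeTrain
from ._common import DEFAULT_N_AFFERENTS, DEFAULT_WINDOW, default_target

__all__ = ["ClassifyResult", "classify_absolute", "classify_relative",
           "run_classification"]


def classify_absolute(outputs: Sequence[SpikeTrain], desired: Sequence[SpikeTrain],
                      true_class: int, mp: MetricParams | None = None,
                      threshold: float = THRESHOLD_MULTI_SPIKE) -> bool:
    """Correct iff the true-class neuron's output is within ``threshold`` of its target."""
    d = van_rossum_distance(outputs[true_class], desired[true_class], mp)
    return d < threshold


def classify_relative(outputs: Sequence[SpikeTrain], desired: Sequence[SpikeTrain],
                      mp: MetricParams | None = None) -> int:
    """Winning neuron: arg-min distance to its own target (ties -> lowest index)."""
    if len(outputs) < 2:
        raise ValueError("relative confidence needs at least two category neurons")
    dists = [van_rossum_distance(o, d, mp) for o, d in zip(outputs, desired)]
    return int(np.argmin(dists))


@dataclass
class ClassifyResult:
    """Per-category and mean accuracies under both criteria."""

    train_absolute: np.ndarray
    test_absolute: np.ndarray
    train_relative: np.ndarray
    test_relative: np.ndarray

    @property
    def mean_train_absolute(self) -> float:
        return float(self.train_absolute.mean())

    @property
    def mean_test_absolute(self) -> float:
        return float(self.test_absolute.mean())

    @property
    def mean_train_relative(self) -> float:
        return float(self.train_relative.mean())

    @property
    def mean_test_relative(self) -> float:
        return float(self.test_relative.mean())


def run_classification(n_categories: int = 3, n_train: int = 20, n_test: int = 40,
                       sigma: float = 2.0,
                       n_afferents: int = DEFAULT_N_AFFERENTS,
                       window: float = DEFAULT_WINDOW,
                       epochs: int = 100,
                       cfg: PSDConfig | None = None,
                       lif: LIFParams | None = None,
                       seed: int = 0) -> ClassifyResult:
    """Full classification experiment for one seed."""
    cfg = cfg or PSDConfig()
    cfg = PSDConfig(eta=cfg.eta, kernel=cfg.kernel, w_max=cfg.w_max,
                    max_epochs=epochs,
                    convergence_distance=cfg.convergence_distance,
                    update_mode=cfg.update_mode, tau_metric=cfg.tau_metric,
                    dt=cfg.dt)
    lif = lif or LIFParams()
    rng = RngSpec(seed, "classify")
    spec = PatternSpec(n_afferents=n_afferents, window=window,
                       mode="single_uniform")
    # templates drawn once; train and test instances are fresh jitters of them
    templates, train_set = make_category_set(n_categories, n_train, spec, sigma,
                                             rng.child("sets"))
    from ..datagen import jitter_pattern
    gen = rng.child("test-jitter").generator()
    test_set = [(jitter_pattern(t, sigma, gen), c)
                for c, t in enumerate(templates) for _ in range(n_test)]

    target = default_target(window)
    silent = SpikeTrain([], window)
    mp = cfg.metric

    weights = []
    patterns = [p for p, _ in train_set]
    for k in range(n_categories):
        desired = [target if c == k else silent for _, c in train_set]
        syn = initial_weights(n_afferents, window, cfg.kernel, lif, cfg.w_max,
                              rng.child(f"w{k}"))
        rec = train_pattern_set(patterns, desired, syn, lif, cfg,
                                rng.child(f"train{k}"))
        weights.append(rec.weights_final)

    desired_own = [target] * n_categories

    def evaluate(instances):
        n_abs = np.zeros(n_categories)
        n_rel = np.zeros(n_categories)
        n_per = np.zeros(n_categories)
        from ..neurons import SynapticState, simulate_lif
        for pat, c in instances:
            outs = []
            for k in range(n_categories):
                syn = SynapticState(weights[k], cfg.w_max)
                _, out = simulate_lif(pat, syn, lif, cfg.kernel, None, cfg.dt)
                outs.append(out)
            n_per[c] += 1
            n_abs[c] += classify_absolute(outs, desired_own, c, mp)
            n_rel[c] += classify_relative(outs, desired_own, mp) == c
        return n_abs / n_per, n_rel / n_per

    train_abs, train_rel = evaluate(train_set)
    test_abs, test_rel = evaluate(test_set)
    return ClassifyResult(train_abs, test_abs, train_rel, test_rel)
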