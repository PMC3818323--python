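"""Hetero-association of one spatiotemporal pattern with a target spike train.

Three protocols:

* :func:`run_association` — train a neuron on one random pattern
  (single-spike or Poisson multi-spike afferents) against the default
  evenly spaced 4-spike target and record the distance trajectory.
* :func:`run_retarget` — after convergence, swap in a fresh random target and
  keep training; the neuron adapts its firing from the old to the new target.
* :func:`run_generality` — train the LIF and the Izhikevich neuron on the
  same pattern, same target and same initial weights; both models should end
  within the multi-spike correctness level of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datagen import PatternSpec, generate_pattern
from ..neurons import IMParams, LIFParams
from ..psd import PSDConfig, TrainRecord, initial_weights, train_one_pattern
from ..spike_core import RngSpec, SpikeTrain
from ._common import DEFAULT_N_AFFERENTS, DEFAULT_WINDOW, default_target

__all__ = ["run_association", "run_retarget", "run_generality",
           "GeneralityResult"]


def _setup(seed: int, n_afferents: int, window: float, mode: str,
           cfg: PSDConfig, lif: LIFParams):
    rng = RngSpec(seed, "assoc")
    spec = PatternSpec(n_afferents=n_afferents, window=window, mode=mode,
                       rng=rng.child("pattern"))
    pattern = generate_pattern(spec)
    syn = initial_weights(n_afferents, window, cfg.kernel, lif, cfg.w_max,
                          rng.child("weights"))
    return rng, pattern, syn


def run_association(seed: int = 0, n_afferents: int = DEFAULT_N_AFFERENTS,
                    window: float = DEFAULT_WINDOW, mode: str = "single_uniform",
                    cfg: PSDConfig | None = None,
                    lif: LIFParams | None = None,
                    target: SpikeTrain | None = None,
                    record_weights: bool = False) -> TrainRecord:
    """Train one LIF neuron to reproduce the target train from one pattern."""
    cfg = cfg or PSDConfig()
    lif = lif or LIFParams()
    rng, pattern, syn = _setup(seed, n_afferents, window, mode, cfg, lif)
    target = target or default_target(window)
    return train_one_pattern(pattern, target, syn, lif, cfg, rng.child("train"),
                             record_weights=record_weights)


def run_retarget(seed: int = 0, n_afferents: int = DEFAULT_N_AFFERENTS,
                 window: float = DEFAULT_WINDOW,
                 cfg: PSDConfig | None = None,
                 lif: LIFParams | None = None) -> tuple[TrainRecord, TrainRecord]:
    """Train to one target, then adapt the converged neuron to a new random target."""
    cfg = cfg or PSDConfig()
    lif = lif or LIFParams()
    rng, pattern, syn = _setup(seed, n_afferents, window, "single_uniform", cfg, lif)
    first = train_one_pattern(pattern, default_target(window), syn, lif, cfg,
                              rng.child("train1"))
    gen = rng.child("retarget").generator()
    n_new = int(gen.integers(3, 6))
    lo = 2.0 * lif.t_ref
    new_times = np.sort(gen.uniform(0.05 * window, 0.95 * window, size=n_new))
    while np.any(np.diff(new_times) <= lo):
        new_times = np.sort(gen.uniform(0.05 * window, 0.95 * window, size=n_new))
    new_target = SpikeTrain(new_times, window)
    from ..neurons import SynapticState
    syn2 = SynapticState(first.weights_final, cfg.w_max)
    second = train_one_pattern(pattern, new_target, syn2, lif, cfg,
                               rng.child("train2"))
    return first, second


@dataclass
class GeneralityResult:
    lif_record: TrainRecord
    im_record: TrainRecord
    lif_distance: float = field(init=False)
    im_distance: float = field(init=False)

    def __post_init__(self) -> None:
        self.lif_distance = self.lif_record.distance_per_epoch[-1]
        self.im_distance = self.im_record.distance_per_epoch[-1]


def run_generality(seed: int = 0, n_afferents: int = DEFAULT_N_AFFERENTS,
                   window: float = DEFAULT_WINDOW,
                   cfg: PSDConfig | None = None,
                   lif: LIFParams | None = None,
                   im: IMParams | None = None) -> GeneralityResult:
    """Same pattern, target and initial weights for both neuron models.

    The convergence level is the multi-spike correctness threshold (0.5):
    the Izhikevich neuron's intrinsic dynamics bound its timing precision
    more loosely than the LIF's.
    """
    cfg = cfg or PSDConfig(convergence_distance=0.5)
    lif = lif or LIFParams()
    im = im or IMParams()
    rng, pattern, syn = _setup(seed, n_afferents, window, "single_uniform", cfg, lif)
    target = default_target(window)
    rec_lif = train_one_pattern(pattern, target, syn.copy(), lif, cfg,
                                rng.child("train-lif"))
    rec_im = train_one_pattern(pattern, target, syn.copy(), im, cfg,
                               rng.child("train-im"))
    return GeneralityResult(rec_lif, rec_im)
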