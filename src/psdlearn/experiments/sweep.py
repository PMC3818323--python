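"""Learning-parameter sweep: learning rate eta x kernel time constant tau_s.

A single LIF neuron is trained to associate 10 random single-spike patterns
with the common 4-spike target; for each (eta, tau_s) cell the epochs to
memorize all patterns (500-epoch budget, failure at the budget) are averaged
over runs.  A suitable tau_s admits a wide range of fast-learning eta; eta
above a critical value (around 0.1 at the default tau_s) slows or breaks
learning, and smaller tau_s concentrates the trained weights on fewer causal
synapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datagen import PatternSpec, generate_pattern
from ..kernels import KernelParams
from ..neurons import LIFParams
from ..psd import PSDConfig, initial_weights, train_pattern_set
from ..spike_core import RngSpec
from ._common import DEFAULT_N_AFFERENTS, DEFAULT_WINDOW, default_target

__all__ = ["SweepResult", "run_sweep"]


@dataclass
class SweepResult:
    eta_values: np.ndarray
    tau_s_values: np.ndarray
    mean_epochs: np.ndarray   # shape (n_eta, n_tau); failures count the budget
    failure_rate: np.ndarray


def run_sweep(eta_values=(0.005, 0.01, 0.02, 0.05, 0.1, 0.2),
              tau_s_values=(2.5, 5.0, 10.0),
              n_patterns: int = 10, runs: int = 5,
              n_afferents: int = DEFAULT_N_AFFERENTS,
              window: float = DEFAULT_WINDOW,
              max_epochs: int = 500,
              convergence_distance: float = 0.2,
              seed: int = 0,
              lif: LIFParams | None = None) -> SweepResult:
    """Grid of mean epochs-to-memorize over (eta, tau_s)."""
    eta_values = np.asarray(eta_values, dtype=float)
    tau_s_values = np.asarray(tau_s_values, dtype=float)
    lif = lif or LIFParams()
    master = RngSpec(seed, "sweep")
    target = default_target(window)
    mean_epochs = np.empty((eta_values.size, tau_s_values.size))
    failure = np.empty_like(mean_epochs)
    for ti, tau_s in enumerate(tau_s_values):
        kernel = KernelParams.from_ratio(tau_s=tau_s)
        for ei, eta in enumerate(eta_values):
            cfg = PSDConfig(eta=eta, kernel=kernel, max_epochs=max_epochs,
                            convergence_distance=convergence_distance)
            epochs = []
            fails = 0
            for r in range(runs):
                rng = master.child(f"t{ti}e{ei}r{r}")
                gen = rng.generator()
                spec = PatternSpec(n_afferents=n_afferents, window=window,
                                   mode="single_uniform")
                patterns = [generate_pattern(spec, gen)
                            for _ in range(n_patterns)]
                syn = initial_weights(n_afferents, window, kernel, lif,
                                      cfg.w_max, rng.child("w"))
                rec = train_pattern_set(patterns, [target] * n_patterns, syn,
                                        lif, cfg, rng.child("train"))
                if rec.converged_epoch is None:
                    fails += 1
                    epochs.append(max_epochs)
                else:
                    epochs.append(rec.converged_epoch)
            mean_epochs[ei, ti] = np.mean(epochs)
            failure[ei, ti] = fails / runs
    return SweepResult(eta_values, tau_s_values, mean_epochs, failure)
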