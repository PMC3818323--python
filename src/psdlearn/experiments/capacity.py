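"""Memory-capacity analysis: maximum and efficient load factors.

The load factor is ``alpha = P / N`` — stored patterns per synapse.  For each
tested load, ``P`` random single-spike patterns over ``N`` afferents are
assigned evenly to ``n_categories`` categories; one LIF neuron is trained to
emit a single spike at the category's time (categories sit at evenly spaced
times in the window) for every pattern, within a budget of 500 epochs.  A
pattern counts as memorized when its van Rossum distance to the category
target is below 0.2; reaching the epoch budget without memorizing all
patterns is a failure.

Two summary loads are derived from the sweep:

* maximum load ``alpha_max`` — the largest tested load at which at least half
  of the runs memorize every pattern;
* efficient load ``alpha_eff`` — the largest tested load whose mean
  epochs-to-success (over successful runs) stays within 100 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..datagen import PatternSpec, generate_pattern
from ..neurons import LIFParams
from ..psd import PSDConfig, initial_weights, train_pattern_set
from ..spike_core import RngSpec
from ._common import DEFAULT_WINDOW, category_target

__all__ = ["LoadResult", "run_capacity", "DEFAULT_LOAD_GRID"]

#: default load grid, step 0.008 patterns/synapse
DEFAULT_LOAD_GRID = tuple(np.round(np.arange(0.080, 0.1761, 0.008), 4))


@dataclass
class LoadResult:
    """Aggregated capacity sweep for one synapse count.

    ``mean_epochs`` averages the epochs each run used, with failed runs
    counted at the epoch budget — this is the quantity whose sharp rise
    marks the capacity limit and the one the efficient-load budget is
    applied to.  ``mean_epochs_success`` averages over successful runs only.
    """

    n_synapses: int
    load_grid: np.ndarray
    mean_epochs: np.ndarray
    sd_epochs: np.ndarray
    failure_rate: np.ndarray
    mean_epochs_success: np.ndarray | None = None
    epochs_all: list[list[int]] = field(repr=False, default_factory=list)
    success_fraction_required: float = 0.5
    efficient_epoch_budget: float = 100.0

    @property
    def max_load(self) -> float:
        """Largest tested load with >= the required fraction of successful runs."""
        ok = (1.0 - self.failure_rate) >= self.success_fraction_required
        return float(self.load_grid[ok].max()) if ok.any() else float("nan")

    @property
    def efficient_load(self) -> float:
        """Largest tested load with mean epochs within the budget."""
        with np.errstate(invalid="ignore"):
            ok = self.mean_epochs <= self.efficient_epoch_budget
        return float(self.load_grid[ok].max()) if ok.any() else float("nan")


def run_capacity(n_synapses: int = 500, n_categories: int = 4,
                 load_grid: Sequence[float] = DEFAULT_LOAD_GRID,
                 runs: int = 10,
                 cfg: PSDConfig | None = None,
                 lif: LIFParams | None = None,
                 window: float = DEFAULT_WINDOW,
                 seed: int = 0) -> LoadResult:
    """Sweep the load grid, ``runs`` independent seeded runs per point."""
    load_grid = np.asarray(sorted(load_grid), dtype=float)
    if np.any(np.diff(load_grid) <= 0):
        raise ValueError("load grid must be strictly ascending")
    cfg = cfg or PSDConfig(max_epochs=500, convergence_distance=0.2)
    lif = lif or LIFParams()
    master = RngSpec(seed, f"capacity-N{n_synapses}")

    targets = [category_target(c, n_categories, window) for c in range(n_categories)]
    mean_e, mean_ok, sd_e, fail = [], [], [], []
    epochs_all: list[list[int]] = []
    for gi, alpha in enumerate(load_grid):
        p = int(round(alpha * n_synapses))
        epochs_used: list[int] = []     # failures count the full budget
        epochs_success: list[int] = []
        for r in range(runs):
            rng = master.child(f"g{gi}r{r}")
            gen = rng.generator()
            spec = PatternSpec(n_afferents=n_synapses, window=window,
                               mode="single_uniform")
            patterns = [generate_pattern(spec, gen) for _ in range(p)]
            cats = np.arange(p) % n_categories
            gen.shuffle(cats)
            desired = [targets[c] for c in cats]
            syn = initial_weights(n_synapses, window, cfg.kernel, lif,
                                  cfg.w_max, rng.child("w"))
            rec = train_pattern_set(patterns, desired, syn, lif, cfg,
                                    rng.child("train"))
            if rec.converged_epoch is None:
                epochs_used.append(cfg.max_epochs)
            else:
                epochs_used.append(rec.converged_epoch)
                epochs_success.append(rec.converged_epoch)
        epochs_all.append(epochs_success)
        mean_e.append(np.mean(epochs_used))
        mean_ok.append(np.mean(epochs_success) if epochs_success else np.nan)
        sd_e.append(np.std(epochs_used))
        fail.append(1.0 - len(epochs_success) / runs)
    return LoadResult(n_synapses, load_grid, np.asarray(mean_e),
                      np.asarray(sd_e), np.asarray(fail), np.asarray(mean_ok),
                      epochs_all)
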