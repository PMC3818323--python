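"""Shared experiment plumbing: default protocol constants and run manifests."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from ..spike_core import SpikeTrain

#: default observation window, ms
DEFAULT_WINDOW = 200.0
#: default number of afferent neurons
DEFAULT_N_AFFERENTS = 500


def default_target(window: float = DEFAULT_WINDOW, n_spikes: int = 4) -> SpikeTrain:
    """Target train with spikes evenly distributed over the window:
    ``T/(n+1) * {1..n}`` — four spikes at 40/80/120/160 ms by default."""
    step = window / (n_spikes + 1)
    return SpikeTrain(step * np.arange(1, n_spikes + 1), window)


def category_target(category: int, n_categories: int,
                    window: float = DEFAULT_WINDOW) -> SpikeTrain:
    """Single desired spike per category at evenly spaced times."""
    step = window / (n_categories + 1)
    return SpikeTrain([step * (category + 1)], window)


def write_manifest(out_dir: Path, name: str, seed: int, config: dict) -> Path:
    """Drop a JSON manifest (config + seed + package version) next to the CSVs."""
    from .. import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"experiment": name, "seed": seed, "version": __version__,
               "config": _jsonable(config)}
    path = out_dir / f"{name}_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
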