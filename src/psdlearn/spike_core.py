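"""Spike-train and spike-pattern containers, serialization and RNG plumbing.

A :class:`SpikeTrain` is a strictly increasing sequence of firing times (ms)
observed in a window ``[0, T]``; a :class:`SpikePattern` stacks one train per
afferent neuron.  These two types are the universal currency of the package:
stimulus generators produce patterns, neuron simulators consume them and emit
trains, and the learning rule and metrics compare trains.

Two plain-text formats are supported for patterns:

* two-column text — header lines ``# n_neurons=<N> window_ms=<T>`` followed by
  one ``<neuron_index> <time_ms>`` line per spike.  Neuron indices are
  1-based in the file (the common neurophysiology convention) and 0-based in
  memory.
* JSON — ``{"window_ms": T, "trains": [[t, ...], ...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "SpikePattern",
    "RngSpec",
    "read_pattern",
    "write_pattern",
    "merge_onto_grid",
]


class PatternFormatError(ValueError):
    """Raised when a pattern file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted firing times of one neuron within an observation window.

    Parameters
    ----------
    times
        Firing times in ms, strictly increasing, all inside ``[0, window]``.
    window
        Duration of the observation interval in ms.
    """

    times: np.ndarray
    window: float

    def __init__(self, times: Iterable[float], window: float) -> None:
        arr = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                         dtype=float)
        arr = np.atleast_1d(arr) if arr.ndim == 0 else arr
        if arr.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError("spike times must be finite")
        window = float(window)
        if window < 0:
            raise ValueError("window must be non-negative")
        if arr.size:
            if arr.min() < 0 or arr.max() > window:
                raise ValueError(
                    f"spike times must lie in [0, {window}]; "
                    f"got range [{arr.min()}, {arr.max()}]"
                )
            if np.any(np.diff(arr) <= 0):
                raise ValueError("spike times must be strictly increasing")
        arr.flags.writeable = False
        object.__setattr__(self, "times", arr)
        object.__setattr__(self, "window", window)

    @classmethod
    def _unchecked(cls, times: np.ndarray, window: float) -> "SpikeTrain":
        """Internal fast path: caller guarantees the invariants hold."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "times", times)
        object.__setattr__(obj, "window", window)
        return obj

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self):
        return iter(self.times)

    def shift(self, dt_ms: float) -> "SpikeTrain":
        """Return a copy with all spikes displaced by ``dt_ms`` (must stay in window)."""
        return SpikeTrain(self.times + dt_ms, self.window)


@dataclass(frozen=True)
class SpikePattern:
    """A stimulus presentation: one :class:`SpikeTrain` per afferent neuron."""

    trains: tuple
    window: float

    def __init__(self, trains: Sequence[SpikeTrain], window: float | None = None) -> None:
        trains = tuple(trains)
        if not trains:
            raise ValueError("a pattern needs at least one afferent")
        if window is None:
            window = trains[0].window
        window = float(window)
        for k, tr in enumerate(trains):
            if tr.window != window:
                raise ValueError(
                    f"train {k} has window {tr.window} ms, pattern window is {window} ms"
                )
        object.__setattr__(self, "trains", trains)
        object.__setattr__(self, "window", window)

    @classmethod
    def _unchecked(cls, trains: tuple, window: float) -> "SpikePattern":
        """Internal fast path: caller guarantees the invariants hold."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "trains", trains)
        object.__setattr__(obj, "window", window)
        return obj

    @property
    def n_afferents(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(len(tr) for tr in self.trains)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(afferent_index, spike_time)`` arrays over all spikes."""
        idx = np.concatenate(
            [np.full(len(tr), i, dtype=np.int64) for i, tr in enumerate(self.trains)]
        ) if self.n_spikes else np.empty(0, dtype=np.int64)
        t = np.concatenate([tr.times for tr in self.trains]) if self.n_spikes \
            else np.empty(0, dtype=float)
        return idx, t


@dataclass(frozen=True)
class RngSpec:
    """Seeded, labelled random stream.

    Identical ``(seed, label)`` pairs reproduce identical draws; distinct
    labels derived from one seed give independent streams.
    """

    seed: int
    label: str = ""

    def generator(self) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=())
        if self.label:
            # fold the label into the entropy so streams with different
            # labels are independent
            digest = np.frombuffer(self.label.encode("utf-8").ljust(4, b"\0"), dtype=np.uint8)
            ss = np.random.SeedSequence([self.seed, int(digest.sum()), len(self.label),
                                         *digest.tolist()])
        return np.random.default_rng(ss)

    def child(self, label: str) -> "RngSpec":
        sub = self.label + "/" + label if self.label else label
        return RngSpec(self.seed, sub)


def merge_onto_grid(train: SpikeTrain, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Map spike times onto simulation grid bins of width ``dt``.

    Bins are half-open ``[k*dt, (k+1)*dt)``; a spike exactly at the window
    boundary goes to the last bin so it is never lost.  Returns
    ``(indices, counts)`` with ascending unique indices and per-bin spike
    multiplicity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(train) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n_bins = max(int(np.ceil(train.window / dt)), 1)
    idx = np.floor(train.times / dt).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)  # t == window falls in the closed last bin
    return np.unique(idx, return_counts=True)


# ---------------------------------------------------------------------------
# serialization


def write_pattern(pattern: SpikePattern, path, fmt: str = "two-column") -> None:
    """Write a pattern as two-column text or JSON (≥ 9 significant digits)."""
    path = Path(path)
    if fmt == "two-column":
        lines = [f"# n_neurons={pattern.n_afferents} window_ms={pattern.window!r}"]
        for i, tr in enumerate(pattern.trains):
            for t in tr.times:
                lines.append(f"{i + 1} {float(t)!r}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = {
            "window_ms": pattern.window,
            "trains": [tr.times.tolist() for tr in pattern.trains],
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown pattern format: {fmt!r}")


def read_pattern(path, fmt: str | None = None) -> SpikePattern:
    """Read a pattern written by :func:`write_pattern`.

    ``fmt`` is inferred from the file suffix when omitted (``.json`` → JSON,
    anything else → two-column).  Out-of-order times within a neuron are
    sorted; duplicate (neuron, time) pairs are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "two-column"
    if fmt == "json":
        payload = json.loads(path.read_text())
        window = float(payload["window_ms"])
        return SpikePattern(
            [SpikeTrain(np.sort(np.asarray(ts, dtype=float)), window)
             for ts in payload["trains"]],
            window,
        )
    if fmt != "two-column":
        raise ValueError(f"unknown pattern format: {fmt!r}")

    n_neurons = None
    window = None
    per_neuron: dict[int, list[float]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("n_neurons="):
                    n_neurons = int(tok.split("=", 1)[1])
                elif tok.startswith("window_ms="):
                    window = float(tok.split("=", 1)[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PatternFormatError(f"{path}:{lineno}: expected '<neuron> <time>', got {raw!r}")
        try:
            idx = int(parts[0])
            t = float(parts[1])
        except ValueError as exc:
            raise PatternFormatError(f"{path}:{lineno}: {exc}") from exc
        if not np.isfinite(t):
            raise PatternFormatError(f"{path}:{lineno}: non-finite spike time")
        per_neuron.setdefault(idx - 1, []).append(t)

    if n_neurons is None or window is None:
        raise PatternFormatError(f"{path}: missing '# n_neurons=... window_ms=...' header")
    trains = []
    for i in range(n_neurons):
        ts = np.sort(np.asarray(per_neuron.get(i, []), dtype=float))
        if ts.size and np.any(np.diff(ts) == 0):
            raise PatternFormatError(f"{path}: duplicate spike time for neuron {i + 1}")
        if ts.size and (ts.min() < 0 or ts.max() > window):
            raise PatternFormatError(
                f"{path}: spike time outside [0, {window}] for neuron {i + 1}"
            )
        trains.append(SpikeTrain(ts, window))
    return SpikePattern(trains, window)
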