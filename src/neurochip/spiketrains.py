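"""Spike-train representations of binary transistor activity.

A "spike" is the off-to-on transition of a transistor's conduction state —
the closest analogue of a discrete action potential.  Conduction state rather
than wire voltage is used; analysing wire values would be the analogue of
measuring transmembrane voltage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .simulator import StateTrace

__all__ = [
    "SpikeSet",
    "BinnedActivity",
    "extract_spikes",
    "extract_switch_events",
    "bin_counts",
    "sliding_rate",
    "zscore",
]

log = logging.getLogger(__name__)


@dataclass
class SpikeSet:
    """Ordered rising-edge event times (timesteps) per unit."""

    events: dict[int, np.ndarray]  # unit id -> strictly increasing int64 times
    length: int  # trace length in timesteps

    @property
    def unit_ids(self) -> tuple[int, ...]:
        return tuple(self.events)

    @property
    def n_units(self) -> int:
        return len(self.events)

    def total_count(self) -> int:
        return sum(len(v) for v in self.events.values())

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("spikes")
            g.attrs["length"] = self.length
            for uid, times in self.events.items():
                g.create_dataset(f"unit_{uid}", data=times, dtype="i8")

    @classmethod
    def load(cls, path: str | Path) -> "SpikeSet":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["spikes"]
            events = {
                int(name.split("_", 1)[1]): g[name][...].astype(np.int64)
                for name in g
            }
            return cls(events=dict(sorted(events.items())),
                       length=int(g.attrs["length"]))


@dataclass
class BinnedActivity:
    """units x bins count matrix (optionally z-scored)."""

    counts: np.ndarray  # (n_units, n_bins)
    bin_width: int
    unit_ids: tuple[int, ...]
    zscored: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("binned", data=self.counts)
            d.attrs["bin_width"] = self.bin_width
            d.attrs["zscored"] = self.zscored
            f.create_dataset("unit_ids", data=np.asarray(self.unit_ids))

    @classmethod
    def load(cls, path: str | Path) -> "BinnedActivity":
        import h5py

        with h5py.File(path, "r") as f:
            d = f["binned"]
            return cls(
                counts=d[...],
                bin_width=int(d.attrs["bin_width"]),
                unit_ids=tuple(int(i) for i in f["unit_ids"][...]),
                zscored=bool(d.attrs["zscored"]),
            )


def _rising_edges(col: np.ndarray) -> np.ndarray:
    """Times t with state[t-1] == 0 and state[t] == 1."""
    prev = np.concatenate(([0], col[:-1]))
    return np.flatnonzero((prev == 0) & (col == 1)).astype(np.int64)


def extract_spikes(trace: StateTrace | np.ndarray,
                   unit_ids: Sequence[int] | None = None) -> SpikeSet:
    """Exact off->on transition times of every transistor.

    Accepts a :class:`StateTrace` (uses conduction states) or a raw binary
    (T, n_units) matrix.  The initial state counts as preceding "off", so a
    unit that is on at t=0 spikes at t=0.
    """
    if isinstance(trace, StateTrace):
        mat = trace.transistor_on
        ids = trace.transistor_ids
    else:
        mat = np.asarray(trace)
        ids = tuple(range(mat.shape[1])) if unit_ids is None else tuple(unit_ids)
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("trace must be binary")
    events = {uid: _rising_edges(mat[:, j]) for j, uid in enumerate(ids)}
    return SpikeSet(events=events, length=mat.shape[0])


def extract_switch_events(trace: StateTrace | np.ndarray,
                          unit_ids: Sequence[int] | None = None,
                          edges: str = "both") -> SpikeSet:
    """Switching events per transistor: both edges by default.

    ``edges`` in {"both", "rising"}; "both" counts on->off as well as off->on
    transitions (the field-potential notion of switching activity).
    """
    if edges not in ("both", "rising"):
        raise ValueError("edges must be 'both' or 'rising'")
    if edges == "rising":
        return extract_spikes(trace, unit_ids)
    if isinstance(trace, StateTrace):
        mat = trace.transistor_on
        ids = trace.transistor_ids
    else:
        mat = np.asarray(trace)
        ids = tuple(range(mat.shape[1])) if unit_ids is None else tuple(unit_ids)
    events = {}
    for j, uid in enumerate(ids):
        col = mat[:, j]
        prev = np.concatenate(([0], col[:-1]))
        events[uid] = np.flatnonzero(prev != col).astype(np.int64)
    return SpikeSet(events=events, length=mat.shape[0])


def bin_counts(spikes: SpikeSet, bin_width: int = 100,
               T: int | None = None) -> BinnedActivity:
    """Count events per unit in consecutive ``bin_width``-timestep bins.

    The total count over bins equals the total spike count (conservation),
    except that a trailing partial bin is dropped (and logged) when ``T`` is
    not a multiple of ``bin_width``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if T is None:
        T = spikes.length
    n_bins = T // bin_width
    if T % bin_width:
        log.warning(
            "trace length %d not a multiple of bin width %d; dropping the "
            "trailing partial bin", T, bin_width,
        )
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros((spikes.n_units, n_bins), dtype=np.int64)
    for row, uid in enumerate(spikes.unit_ids):
        times = spikes.events[uid]
        times = times[times < n_bins * bin_width]
        counts[row] = np.histogram(times, bins=edges)[0]
    return BinnedActivity(counts=counts, bin_width=bin_width,
                          unit_ids=spikes.unit_ids)


def sliding_rate(spikes: SpikeSet, window: int = 100,
                 T: int | None = None) -> np.ndarray:
    """Trailing-window rate: rate[u, t] = #events of u in (t-window, t].

    Mirrors summing activity over the preceding ``window`` timesteps.
    Returns an (n_units, T) array.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if T is None:
        T = spikes.length
    rates = np.zeros((spikes.n_units, T), dtype=np.int64)
    t = np.arange(T)
    lo = np.maximum(t + 1 - window, 0)
    for row, uid in enumerate(spikes.unit_ids):
        times = spikes.events[uid]
        times = times[times < T]
        impulses = np.bincount(times, minlength=T)
        cum = np.concatenate(([0], np.cumsum(impulses)))  # cum[k] = events < k
        rates[row] = cum[t + 1] - cum[lo]
    return rates


def zscore(binned: BinnedActivity) -> BinnedActivity:
    """Row-wise z-score with the population (1/N) variance convention.

    Constant rows map to all zeros.  Idempotent on already-z-scored
    non-constant rows.
    """
    x = binned.counts.astype(float)
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, keepdims=True)  # population convention
    out = np.zeros_like(x)
    nz = std[:, 0] > 0
    out[nz] = (x[nz] - mean[nz]) / std[nz]
    return BinnedActivity(counts=out, bin_width=binned.bin_width,
                          unit_ids=binned.unit_ids, zscored=True)
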