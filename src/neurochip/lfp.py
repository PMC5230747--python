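"""Local-field-potential analogues: spatially weighted switching and spectra.

An LFP channel spatially integrates transistor switching around a recording
point with a Gaussian weight of scale sigma (default 500 um) and low-passes
the result with a moving-average window (default 4 timesteps).  "Switching"
counts both conduction edges (off->on and on->off) by default, which is
distinct from the rising-edge spike definition; a flag restricts it to
rising edges.

Spectra use Welch's method with 256-sample windows, a Hann taper, and no
overlap.  Frequencies are in cycles/timestep (Nyquist 0.5); multiply by a
clock rate to convert to physical units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .spiketrains import SpikeSet

__all__ = ["LFPChannel", "Spectrum", "lfp_channel", "periodogram",
           "events_to_counts", "moving_average"]

log = logging.getLogger(__name__)

SIGMA_DEFAULT = 500.0  # um
LOWPASS_WIDTH_DEFAULT = 4  # timesteps
WELCH_NPERSEG = 256


@dataclass
class LFPChannel:
    """A spatially localized aggregate switching signal."""

    center: tuple[float, float]
    sigma: float
    lowpass_width: int
    samples: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.samples.shape[0]


@dataclass
class Spectrum:
    """Welch power spectral density on a cycles/timestep grid."""

    frequencies: np.ndarray
    power: np.ndarray
    settings: dict = field(default_factory=dict)

    @property
    def argmax_frequency(self) -> float:
        """Frequency of peak power, ignoring the DC bin."""
        nonzero = self.frequencies > 0
        idx = np.flatnonzero(nonzero)[int(np.argmax(self.power[nonzero]))]
        return float(self.frequencies[idx])


def events_to_counts(events: SpikeSet) -> np.ndarray:
    """Per-unit event-count time series, shape (n_units, T)."""
    out = np.zeros((events.n_units, events.length), dtype=float)
    for row, uid in enumerate(events.unit_ids):
        times = events.events[uid]
        times = times[times < events.length]
        out[row] = np.bincount(times, minlength=events.length)
    return out


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered boxcar average; edge windows truncated to available samples.

    For even widths the window covers [t - width//2, t + width//2 - 1].
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    cum = np.concatenate(([0.0], np.cumsum(x)))
    t = np.arange(T)
    lo = np.clip(t - width // 2, 0, T)
    hi = np.clip(t + (width - 1) // 2 + 1, 0, T)
    return (cum[hi] - cum[lo]) / (hi - lo)


def lfp_channel(events: SpikeSet | np.ndarray,
                positions: np.ndarray,
                center: tuple[float, float],
                sigma: float = SIGMA_DEFAULT,
                lowpass_width: int = LOWPASS_WIDTH_DEFAULT) -> LFPChannel:
    """Gaussian-weighted sum of per-unit switching, then low-passed.

    ``events`` is a switch-event :class:`SpikeSet` (both-edge events for the
    standard LFP) or a precomputed (n_units, T) count matrix.  ``positions``
    is (n_units, 2) in layout micrometres.  Weight for a unit at distance d
    is exp(-d^2 / (2 sigma^2)); a channel with no unit within 4 sigma is
    returned as all zeros with a warning.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    counts = events_to_counts(events) if isinstance(events, SpikeSet) else np.asarray(events, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (counts.shape[0], 2):
        raise ValueError("positions must be (n_units, 2)")
    center_arr = np.asarray(center, dtype=float)
    d2 = ((positions - center_arr) ** 2).sum(axis=1)
    weights = np.exp(-d2 / (2.0 * sigma ** 2))
    if not (d2 <= (4.0 * sigma) ** 2).any():
        log.warning("no transistors within 4 sigma of channel center %s; "
                    "channel is zero", tuple(center_arr))
        samples = np.zeros(counts.shape[1])
    else:
        raw = weights @ counts
        samples = moving_average(raw, lowpass_width)
    return LFPChannel(center=(float(center_arr[0]), float(center_arr[1])),
                      sigma=float(sigma), lowpass_width=int(lowpass_width),
                      samples=samples)


def periodogram(channel: LFPChannel | np.ndarray,
                nperseg: int = WELCH_NPERSEG) -> Spectrum:
    """Welch PSD: Hann window, ``nperseg``-sample segments, no overlap."""
    x = channel.samples if isinstance(channel, LFPChannel) else np.asarray(channel, dtype=float)
    nperseg = min(nperseg, x.shape[0])
    freqs, power = welch(x, fs=1.0, window="hann", nperseg=nperseg,
                         noverlap=0, detrend="constant")
    return Spectrum(
        frequencies=freqs,
        power=power,
        settings={"window": "hann", "nperseg": nperseg, "noverlap": 0,
                  "detrend": "constant"},
    )
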