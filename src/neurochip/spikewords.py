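"""Population synchrony statistics: spike words and shuffle controls.

A spike word is the binary population vector of which units are active in one
time bin; its weight is the number of active units.  Weak pairwise
correlations can coexist with strongly non-independent word-weight
distributions, which is exactly what the shuffle control exposes: shuffling
destroys cross-unit alignment while preserving every unit's marginal count,
so for truly independent units the shuffled and raw weight histograms agree
up to sampling error, while common-driver synchrony makes them diverge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spiketrains import BinnedActivity

__all__ = [
    "WordStats",
    "select_units",
    "word_stats",
    "shuffle_control",
    "tv_distance",
    "word_weight_histogram",
]


@dataclass
class WordStats:
    """Word-weight histogram, pairwise correlations, and shuffle comparison."""

    unit_ids: tuple[int, ...]
    weight_histogram: np.ndarray  # P(k active units), k = 0..n_units
    correlations: np.ndarray  # (n, n) Pearson matrix, unit diagonal
    shuffled_histogram: np.ndarray | None = None
    tv_divergence: float | None = None

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def histogram_frame(self):
        import pandas as pd

        rows = {"weight": np.arange(len(self.weight_histogram)),
                "p_raw": self.weight_histogram}
        if self.shuffled_histogram is not None:
            rows["p_shuffled"] = self.shuffled_histogram
        return pd.DataFrame(rows)


def select_units(binned: BinnedActivity, n: int = 64,
                 seed: int | None = None) -> tuple[int, ...]:
    """The ``n`` units whose mean rates are nearest the population mean rate.

    Ties are broken by unit id (lower first), so the selection is
    deterministic; ``seed`` is accepted for interface symmetry and only
    matters if a caller subsamples among exact ties externally.
    """
    rates = binned.counts.mean(axis=1)
    target = rates.mean()
    order = sorted(range(len(rates)),
                   key=lambda i: (abs(rates[i] - target), binned.unit_ids[i]))
    if n > len(order):
        raise ValueError(f"requested {n} units but only {len(order)} available")
    chosen = sorted(order[:n], key=lambda i: binned.unit_ids[i])
    return tuple(binned.unit_ids[i] for i in chosen)


def _binarize(word_matrix: np.ndarray) -> np.ndarray:
    mat = np.asarray(word_matrix)
    return (mat > 0).astype(np.int8)


def word_weight_histogram(word_matrix: np.ndarray) -> np.ndarray:
    """P(k active units per bin) for k = 0..n_units; sums to one."""
    mat = _binarize(word_matrix)
    n_units, n_bins = mat.shape
    weights = mat.sum(axis=0)
    hist = np.bincount(weights, minlength=n_units + 1).astype(float)
    return hist / n_bins


def word_stats(word_matrix: np.ndarray,
               unit_ids: Sequence[int] | None = None,
               seed: int | None = None,
               shuffle: bool = True) -> WordStats:
    """Weight histogram and pairwise correlations of a binary word matrix.

    ``word_matrix`` is (n_units, n_bins); nonzero entries count as active.
    When ``shuffle`` is set the circular-shift control is computed and the
    total-variation divergence between raw and shuffled weight histograms
    reported.
    """
    mat = _binarize(word_matrix)
    n_units = mat.shape[0]
    ids = tuple(unit_ids) if unit_ids is not None else tuple(range(n_units))
    hist = word_weight_histogram(mat)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    # constant units have undefined correlation; define it as 0 off-diagonal
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    shuffled_hist = None
    tv = None
    if shuffle:
        shuffled = shuffle_control(mat, seed=seed if seed is not None else 0)
        shuffled_hist = word_weight_histogram(shuffled)
        tv = tv_distance(hist, shuffled_hist)
    return WordStats(
        unit_ids=ids,
        weight_histogram=hist,
        correlations=corr,
        shuffled_histogram=shuffled_hist,
        tv_divergence=tv,
    )


def shuffle_control(word_matrix: np.ndarray, seed: int = 0,
                    method: str = "circular") -> np.ndarray:
    """Destroy cross-unit alignment while preserving per-unit marginals.

    ``circular`` (default) applies an independent uniform circular time shift
    to each unit, preserving both marginal counts and autocorrelation.
    ``permute_bins`` independently permutes each unit's bins instead
    (preserves counts only).
    """
    mat = np.asarray(word_matrix)
    rng = np.random.default_rng(seed)
    out = np.empty_like(mat)
    n_units, n_bins = mat.shape
    if method == "circular":
        shifts = rng.integers(0, n_bins, size=n_units)
        for i in range(n_units):
            out[i] = np.roll(mat[i], int(shifts[i]))
    elif method == "permute_bins":
        for i in range(n_units):
            out[i] = mat[i, rng.permutation(n_bins)]
    else:
        raise ValueError(f"unknown shuffle method {method!r}")
    return out


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two discrete distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return 0.5 * float(np.abs(p - q).sum())
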