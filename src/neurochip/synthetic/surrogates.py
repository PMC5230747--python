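"""Seed-deterministic surrogate data generators with planted ground truth.

Each generator plants a known structure — a directed VAR causal graph,
unimodal Poisson-style tuning, low-rank non-negative factors, block-model
connectivity, or common-driver population synchrony — so the corresponding
analysis stage can be scored against truth.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..connectomics import RELATION_NAMES, RelationGraphs
from ..spiketrains import SpikeSet
from ..tuning import StimulusTrace

__all__ = [
    "gen_var",
    "gen_tuned_spikes",
    "gen_block_stimulus",
    "gen_planted_nmf",
    "gen_planted_sbm",
    "gen_word_matrix",
]


def _companion_spectral_radius(coefficients: np.ndarray) -> float:
    p, m, _ = coefficients.shape
    comp = np.zeros((p * m, p * m))
    for lag in range(p):
        comp[:m, lag * m:(lag + 1) * m] = coefficients[lag]
    if p > 1:
        comp[m:, :-m] = np.eye((p - 1) * m)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def gen_var(coefficients: np.ndarray, noise_cov: np.ndarray,
            n_trials: int, trial_length: int, seed: int = 0,
            burn_in: int = 100) -> np.ndarray:
    """Simulate trials from a stationary VAR process with known coefficients.

    ``coefficients`` is (p, m, m) with [lag, target, source] orientation;
    trials are independent, each started from its own burn-in.  Raises if
    the companion matrix has spectral radius >= 1 (non-stationary).
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.ndim != 3 or coefficients.shape[1] != coefficients.shape[2]:
        raise ValueError("coefficients must be (p, m, m)")
    p, m, _ = coefficients.shape
    noise_cov = np.asarray(noise_cov, dtype=float)
    if noise_cov.shape != (m, m):
        raise ValueError("noise covariance must be (m, m)")
    radius = _companion_spectral_radius(coefficients) if p else 0.0
    if radius >= 1.0:
        raise ValueError(
            f"VAR is non-stationary: companion spectral radius {radius:.3f} >= 1"
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(noise_cov + 1e-15 * np.eye(m))
    total = burn_in + trial_length
    out = np.empty((n_trials, m, trial_length))
    for trial in range(n_trials):
        eps = rng.standard_normal((total, m)) @ chol.T
        y = np.zeros((total, m))
        for t in range(total):
            acc = eps[t].copy()
            for lag in range(min(p, t)):
                acc += coefficients[lag] @ y[t - lag - 1]
            y[t] = acc
        out[trial] = y[burn_in:].T
    return out


def gen_block_stimulus(n_steps: int, values: Sequence[float],
                       block_length: int = 200, seed: int = 0) -> StimulusTrace:
    """Piecewise-constant stimulus: i.i.d. uniform draws held over blocks.

    Dwell blocks give the trailing rate window time to reflect the current
    stimulus, mimicking a behavior with near-uniform stimulus occupancy.
    """
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n_steps / block_length))
    draws = rng.choice(np.asarray(values, dtype=float), size=n_blocks)
    return StimulusTrace(np.repeat(draws, block_length)[:n_steps])


def gen_tuned_spikes(params: Sequence[tuple[float, float, float, float]],
                     stimulus: StimulusTrace | np.ndarray,
                     seed: int = 0, window: int = 100) -> SpikeSet:
    """Spike trains with planted Gaussian tuning on a shared stimulus.

    Each unit's parameters (a, b, mu, w) set an instantaneous rate
    lambda(s) = a * exp(-(s - mu)^2 / (2 w^2)) + b in expected events per
    ``window`` timesteps; events are Bernoulli per timestep with probability
    lambda(s_t) / window.  A unit with a = 0 is homogeneous Poisson-like at
    baseline rate b.
    """
    stim = stimulus.values if isinstance(stimulus, StimulusTrace) else np.asarray(stimulus, dtype=float)
    rng = np.random.default_rng(seed)
    events = {}
    for uid, (a, b, mu, w) in enumerate(params):
        lam = a * np.exp(-((stim - mu) ** 2) / (2.0 * w ** 2)) + b
        prob = np.clip(lam / window, 0.0, 1.0)
        spikes = rng.random(stim.shape[0]) < prob
        events[uid] = np.flatnonzero(spikes).astype(np.int64)
    return SpikeSet(events=events, length=stim.shape[0])


def gen_planted_nmf(W: np.ndarray, H: np.ndarray, noise_scale: float = 0.0,
                    seed: int = 0) -> np.ndarray:
    """X = W @ H plus truncated Gaussian noise, clipped at zero.

    With ``noise_scale`` 0 the product is returned exactly.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if (W < 0).any() or (H < 0).any():
        raise ValueError("planted factors must be non-negative")
    X = W @ H
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        X = X + noise_scale * rng.standard_normal(X.shape)
        X = np.clip(X, 0.0, None)
    return X


def gen_planted_sbm(block_sizes: Sequence[int], p_in: float, p_out: float,
                    seed: int = 0) -> tuple[RelationGraphs, np.ndarray]:
    """Six independent directed Bernoulli relations over shared planted blocks.

    Returns the relation graphs plus the true label vector.  Edge
    probability is ``p_in`` within a block and ``p_out`` across blocks, for
    every relation; self-edges are excluded.
    """
    if not (0 <= p_out <= 1 and 0 <= p_in <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    n = labels.shape[0]
    rng = np.random.default_rng(seed)
    same = labels[:, None] == labels[None, :]
    probs = np.where(same, p_in, p_out)
    matrices = {}
    for name in RELATION_NAMES:
        mat = (rng.random((n, n)) < probs).astype(np.uint8)
        np.fill_diagonal(mat, 0)
        matrices[name] = mat
    relations = RelationGraphs(matrices=matrices, node_ids=tuple(range(n)))
    return relations, labels


def gen_word_matrix(kind: str, n_units: int = 64, n_bins: int = 10_000,
                    rate: float = 0.1, seed: int = 0,
                    coupling: float = 1.0) -> np.ndarray:
    """Binary population word matrices with known dependence structure.

    ``independent``: i.i.d. Bernoulli(rate) per unit and bin.
    ``common_driver``: a latent Bernoulli(rate) driver is copied by every
    unit with probability ``coupling`` (otherwise the unit draws
    independently), planting population-wide synchrony at matched marginals.
    """
    rng = np.random.default_rng(seed)
    if kind == "independent":
        return (rng.random((n_units, n_bins)) < rate).astype(np.int8)
    if kind == "common_driver":
        driver = (rng.random(n_bins) < rate).astype(np.int8)
        follow = rng.random((n_units, n_bins)) < coupling
        own = (rng.random((n_units, n_bins)) < rate).astype(np.int8)
        return np.where(follow, driver[None, :], own).astype(np.int8)
    raise ValueError(f"unknown word-matrix kind {kind!r}")
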