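"""Trial-based conditional Granger causality between channels.

Channels (typically LFP analogues) are segmented into equal-length trials;
vector autoregressions are fit by least squares jointly over trials — lagged
regressors are stacked across trials so no lag ever crosses a trial boundary.
Conditional Granger causality from X to Y given a conditioning set Z is the
log ratio of Y's residual variance under a model using the past of {Y, Z}
only versus a model that adds the past of X; it is clipped at zero.

Model order is chosen by BIC,

    BIC(p) = ln det(Sigma_p) + ln(N) * p * m^2 / N,

with Sigma_p the pooled maximum-likelihood residual covariance, N the number
of stacked observations, and m the channel count.  The default selection is
the argmin over the candidate orders; a plateau rule (smallest order within a
tolerance of the minimum) is available because published "where BIC
plateaus" judgements are not otherwise reproducible.

Edge significance uses a trial-permutation null: the source channel's trials
are permuted relative to the others, breaking any cross-channel temporal
relation while preserving each channel's within-trial dynamics.  P-values
are Bonferroni-corrected within a behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VARModel",
    "GCGraph",
    "GCEdge",
    "fit_var",
    "select_order",
    "bic",
    "conditional_gc",
    "gc_graph",
    "segment_trials",
]

P_RANGE_DEFAULT = range(1, 32)


class RankDeficientError(np.linalg.LinAlgError):
    pass


@dataclass
class VARModel:
    """VAR(p) least-squares fit pooled over trials."""

    order: int
    coefficients: np.ndarray  # (p, m, m); [lag, target, source]
    intercept: np.ndarray  # (m,)
    residual_covariance: np.ndarray  # (m, m), ML (1/N) convention
    n_obs: int


def _as_trials(trials: np.ndarray) -> np.ndarray:
    arr = np.asarray(trials, dtype=float)
    if arr.ndim == 2:  # single continuous recording: one trial
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("trials must be (n_trials, n_channels, trial_length)")
    if arr.shape[1] < 1:
        raise ValueError("need at least one channel")
    return arr


def segment_trials(channels: np.ndarray, n_trials: int) -> np.ndarray:
    """Cut one long (n_channels, T) recording into equal contiguous trials."""
    channels = np.asarray(channels, dtype=float)
    m, T = channels.shape
    L = T // n_trials
    if L < 2:
        raise ValueError("recording too short for the requested trial count")
    return channels[:, : n_trials * L].reshape(m, n_trials, L).transpose(1, 0, 2)


def _design(trials: np.ndarray, p: int, channels: Sequence[int]):
    """Stacked lagged design over trials for the given predictor channels.

    Returns (X, n_rows): X has one intercept column plus p columns per
    channel, ordered channel-major then lag.
    """
    n_trials, _, L = trials.shape
    if p >= L:
        raise ValueError(f"model order {p} >= trial length {L}")
    rows = n_trials * (L - p)
    cols = [np.ones((rows, 1))]
    for ch in channels:
        for lag in range(1, p + 1):
            cols.append(
                trials[:, ch, p - lag: L - lag].reshape(rows, 1)
            )
    return np.concatenate(cols, axis=1)


def _targets(trials: np.ndarray, p: int, channels: Sequence[int]) -> np.ndarray:
    n_trials, _, L = trials.shape
    rows = n_trials * (L - p)
    return np.stack(
        [trials[:, ch, p:].reshape(rows) for ch in channels], axis=1
    )


def _lstsq(X: np.ndarray, Y: np.ndarray, p: int):
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficientError(
            f"rank-deficient regressor matrix at order {p}; "
            "try a smaller model order"
        )
    resid = Y - X @ coef
    return coef, resid


def fit_var(trials: np.ndarray, p: int) -> VARModel:
    """Least-squares VAR(p) over all trials jointly (no cross-trial lags).

    With ``p=0`` the model is just the per-channel mean and the residual
    covariance is the (population) sample covariance.
    """
    trials = _as_trials(trials)
    m = trials.shape[1]
    if p < 0:
        raise ValueError("order must be >= 0")
    all_ch = list(range(m))
    X = _design(trials, p, all_ch)
    Y = _targets(trials, p, all_ch)
    coef, resid = _lstsq(X, Y, p)
    N = Y.shape[0]
    sigma = resid.T @ resid / N
    coeffs = np.zeros((p, m, m))
    for j, ch in enumerate(all_ch):
        for lag in range(p):
            coeffs[lag, :, ch] = coef[1 + j * p + lag]
    return VARModel(order=p, coefficients=coeffs, intercept=coef[0].copy(),
                    residual_covariance=sigma, n_obs=N)


def bic(model: VARModel, m: int | None = None) -> float:
    """ln det(Sigma) + ln(N) * p * m^2 / N."""
    if m is None:
        m = model.residual_covariance.shape[0]
    N = model.n_obs
    sign, logdet = np.linalg.slogdet(model.residual_covariance)
    if sign <= 0:
        return np.inf
    return float(logdet + np.log(N) * model.order * m * m / N)


def select_order(trials: np.ndarray,
                 p_range: Iterable[int] = P_RANGE_DEFAULT,
                 rule: str = "argmin",
                 plateau_tol: float = 0.01) -> int:
    """Choose the VAR order by BIC over ``p_range``.

    ``rule='argmin'`` (default) returns the BIC-minimizing order.
    ``rule='plateau'`` returns the smallest order whose BIC lies within
    ``plateau_tol`` of the minimum, measured as a fraction of the BIC range
    over the candidates.
    """
    trials = _as_trials(trials)
    orders = list(p_range)
    if not orders:
        raise ValueError("empty order range")

    def _bic_or_inf(p: int) -> float:
        try:
            return bic(fit_var(trials, p))
        except RankDeficientError:
            return np.inf

    bics = np.array([_bic_or_inf(p) for p in orders])
    if not np.isfinite(bics).any():
        raise RankDeficientError(
            "all candidate orders are rank-deficient; the channels may be "
            "deterministic or collinear"
        )
    if rule == "argmin":
        return orders[int(np.argmin(bics))]
    if rule == "plateau":
        spread = float(bics.max() - bics.min()) or 1.0
        threshold = bics.min() + plateau_tol * spread
        for p, b in zip(orders, bics):
            if b <= threshold:
                return p
    raise ValueError(f"unknown selection rule {rule!r}")


def _target_residual_variance(trials, p, target, predictors):
    X = _design(trials, p, predictors)
    y = _targets(trials, p, [target])
    _, resid = _lstsq(X, y, p)
    return float((resid ** 2).sum() / resid.shape[0])


def conditional_gc(trials: np.ndarray, source: int, target: int,
                   conditioning: Sequence[int] = (), p: int = 1) -> float:
    """ln(reduced residual variance / full residual variance), clipped at 0.

    The reduced model predicts the target from the past of the target and the
    conditioning channels; the full model adds the source's past.
    """
    trials = _as_trials(trials)
    conditioning = list(conditioning)
    if source == target:
        raise ValueError("source and target must differ")
    if source in conditioning or target in conditioning:
        raise ValueError("conditioning set must exclude source and target")
    reduced_pred = [target] + conditioning
    full_pred = [target] + [source] + conditioning
    var_reduced = _target_residual_variance(trials, p, target, reduced_pred)
    var_full = _target_residual_variance(trials, p, target, full_pred)
    if var_full <= 0:
        return np.inf if var_reduced > 0 else 0.0
    return max(0.0, float(np.log(var_reduced / var_full)))


@dataclass(frozen=True)
class GCEdge:
    source: int
    target: int
    magnitude: float
    p_value: float
    significant: bool


@dataclass
class GCGraph:
    """Directed conditional-Granger graph over channels (no self-edges)."""

    n_channels: int
    edges: tuple[GCEdge, ...]
    alpha: float
    behavior: str | None = None
    channel_names: tuple[str, ...] | None = None

    def significant_edges(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.source, e.target) for e in self.edges if e.significant)

    def magnitude(self, source: int, target: int) -> float:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.magnitude
        raise KeyError((source, target))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(alpha=self.alpha, behavior=self.behavior or "")
        names = self.channel_names or tuple(str(i) for i in range(self.n_channels))
        for i, name in enumerate(names):
            g.add_node(i, name=name)
        for e in self.edges:
            if e.significant:
                g.add_edge(e.source, e.target, magnitude=e.magnitude,
                           p_value=e.p_value)
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def to_frame(self):
        import pandas as pd

        names = self.channel_names or tuple(str(i) for i in range(self.n_channels))
        return pd.DataFrame(
            [
                {
                    "source": names[e.source],
                    "target": names[e.target],
                    "magnitude": e.magnitude,
                    "p": e.p_value,
                    "significant": e.significant,
                    "behavior": self.behavior or "",
                }
                for e in self.edges
            ]
        )


def permutation_pvalue(trials: np.ndarray, source: int, target: int,
                       conditioning: Sequence[int], p: int,
                       n_permutations: int = 500,
                       seed: int = 0) -> tuple[float, float]:
    """Observed GC magnitude and its trial-permutation p-value.

    The null resamples the source channel's trial order relative to all other
    channels; the reduced model is unaffected by construction.
    """
    trials = _as_trials(trials)
    rng = np.random.default_rng(seed)
    conditioning = list(conditioning)
    n_trials, _, L = trials.shape
    rows_per_trial = L - p
    X_red = _design(trials, p, [target] + conditioning)
    y = _targets(trials, p, [target])[:, 0]
    Q, _ = np.linalg.qr(X_red)
    y_res = y - Q @ (Q.T @ y)
    var_reduced = float((y_res ** 2).mean())
    # source lag block, kept per-trial so the null can permute whole trials
    S = _design(trials, p, [source])[:, 1:]  # drop the intercept column
    S_blocks = S.reshape(n_trials, rows_per_trial, p)

    def full_var(source_block: np.ndarray) -> float:
        s = source_block.reshape(n_trials * rows_per_trial, p)
        s_res = s - Q @ (Q.T @ s)
        beta, *_ = np.linalg.lstsq(s_res, y_res, rcond=None)
        r = y_res - s_res @ beta
        return float((r ** 2).mean())

    if var_reduced <= 0:
        return 0.0, 1.0

    def magnitude(block: np.ndarray) -> float:
        vf = full_var(block)
        if vf <= 0:
            return np.inf
        return max(0.0, float(np.log(var_reduced / vf)))

    observed = magnitude(S_blocks)
    exceed = 0
    for _ in range(n_permutations):
        order = rng.permutation(n_trials)
        if magnitude(S_blocks[order]) >= observed:
            exceed += 1
    pval = (1 + exceed) / (1 + n_permutations)
    return float(observed), float(pval)


def gc_graph(trials: np.ndarray, p: int, alpha: float = 0.01,
             n_permutations: int = 500, seed: int = 0,
             behavior: str | None = None,
             channel_names: Sequence[str] | None = None) -> GCGraph:
    """Conditional GC for every ordered channel pair, permutation-tested.

    Each pair is conditioned on all remaining channels.  Significance is
    Bonferroni-corrected within the behavior: an edge is kept when its
    permutation p-value is at most ``alpha / (m * (m - 1))``.
    """
    trials = _as_trials(trials)
    m = trials.shape[1]
    if m < 2:
        raise ValueError("need at least two channels")
    n_tests = m * (m - 1)
    threshold = alpha / n_tests
    if 1.0 / (n_permutations + 1) > threshold:
        import logging

        logging.getLogger(__name__).warning(
            "smallest achievable permutation p-value 1/%d exceeds the "
            "Bonferroni threshold %.2g; no edge can reach significance — "
            "increase n_permutations", n_permutations + 1, threshold,
        )
    rng = np.random.default_rng(seed)
    edges = []
    for src in range(m):
        for tgt in range(m):
            if src == tgt:
                continue
            cond = [c for c in range(m) if c not in (src, tgt)]
            mag, pval = permutation_pvalue(
                trials, src, tgt, cond, p,
                n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            edges.append(GCEdge(src, tgt, mag, pval, pval <= threshold))
    return GCGraph(n_channels=m, edges=tuple(edges), alpha=alpha,
                   behavior=behavior,
                   channel_names=tuple(channel_names) if channel_names else None)
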