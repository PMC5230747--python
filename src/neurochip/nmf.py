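"""Non-negative matrix factorization of whole-circuit activity.

The activity matrix X (units x time bins, elementwise non-negative) is
approximated by W @ H with W (units x k) and H (k x bins) non-negative,
minimizing the squared Frobenius objective ||X - WH||_F^2.  Optimization is
by multiplicative updates, which never increase the objective, initialized
with non-negative double singular value decomposition (NNDSVDa).  Runs are
reproducible: a fixed seed yields identical factors.

Components are interpreted by correlating each H row against a registry of
known time-varying signals (clock phases, control lines, counter bits, ...)
binned identically, and by mapping each unit to its dominant component —
the argmax of its W row — with the loading magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Factorization",
    "ComponentInterpretation",
    "nmf_fit",
    "interpret_components",
    "match_components",
]

_EPS = 1e-12


@dataclass
class Factorization:
    W: np.ndarray  # (units, k)
    H: np.ndarray  # (k, bins)
    k: int
    objective: list[float]  # ||X - WH||_F^2 per iteration, non-increasing
    seed: int
    converged: bool

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H

    def relative_error(self, X: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        return float(np.linalg.norm(X - self.W @ self.H) / max(np.linalg.norm(X), _EPS))

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("H", data=self.H)
            f.create_dataset("objective", data=np.asarray(self.objective))
            f.attrs["k"] = self.k
            f.attrs["seed"] = self.seed
            f.attrs["converged"] = self.converged


def _nndsvda(X: np.ndarray, k: int, rng: np.random.Generator):
    """Non-negative double SVD initialization, zeros filled with mean(X)."""
    n, m = X.shape
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    r = min(k, len(S))
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, r):
        x, y = U[:, j], Vt[j]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        mp = np.linalg.norm(xp) * np.linalg.norm(yp)
        mn = np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn:
            u = xp / max(np.linalg.norm(xp), _EPS)
            v = yp / max(np.linalg.norm(yp), _EPS)
            sig = mp
        else:
            u = xn / max(np.linalg.norm(xn), _EPS)
            v = yn / max(np.linalg.norm(yn), _EPS)
            sig = mn
        W[:, j] = np.sqrt(S[j] * sig) * u
        H[j] = np.sqrt(S[j] * sig) * v
    avg = X.mean()
    W[W <= 0] = avg
    H[H <= 0] = avg
    if k > r:  # more components than rank: small random fill
        W[:, r:] = avg * rng.random((n, k - r))
        H[r:] = avg * rng.random((k - r, m))
    return W, H


def nmf_fit(X: np.ndarray, k: int = 6, seed: int = 0,
            max_iter: int = 200, tol: float = 1e-4) -> Factorization:
    """Multiplicative-update NMF with NNDSVDa initialization.

    Raises on negative entries in ``X`` — factorize non-negative activity
    (counts or binary states), not z-scored data.  Converged when the
    relative objective decrease falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d array")
    if (X < 0).any():
        raise ValueError(
            "X has negative entries; NMF requires non-negative activity "
            "(use counts or states, not z-scores)"
        )
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k must be in [1, {min(X.shape)}]")
    rng = np.random.default_rng(seed)
    W, H = _nndsvda(X, k, rng)
    objective = [float(np.linalg.norm(X - W @ H) ** 2)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ X) / np.maximum(W.T @ W @ H, _EPS)
        W *= (X @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        obj = float(np.linalg.norm(X - W @ H) ** 2)
        objective.append(obj)
        prev = objective[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return Factorization(W=W, H=H, k=k, objective=objective, seed=seed,
                         converged=converged)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ComponentInterpretation:
    """Signed correlations of components with known signals + dominance map."""

    signal_names: tuple[str, ...]
    correlations: np.ndarray  # (k, n_signals), in [-1, 1]
    dominant_component: np.ndarray  # (n_units,) argmax over each W row
    dominant_magnitude: np.ndarray  # (n_units,)
    positions: np.ndarray | None = None
    unit_ids: tuple[int, ...] | None = None

    def best_match(self, signal: str) -> tuple[int, float]:
        """(component, signed correlation) with the largest |r| for a signal."""
        j = self.signal_names.index(signal)
        col = self.correlations[:, j]
        i = int(np.argmax(np.abs(col)))
        return i, float(col[i])

    def correlation_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.correlations,
            index=[f"component_{i}" for i in range(self.correlations.shape[0])],
            columns=list(self.signal_names),
        )

    def dominance_frame(self):
        import pandas as pd

        ids = self.unit_ids or tuple(range(len(self.dominant_component)))
        df = pd.DataFrame(
            {
                "unit": ids,
                "component": self.dominant_component,
                "magnitude": self.dominant_magnitude,
            }
        )
        if self.positions is not None:
            df["x"] = self.positions[:, 0]
            df["y"] = self.positions[:, 1]
        return df


def interpret_components(factorization: Factorization,
                         known_signals: Mapping[str, np.ndarray],
                         positions: np.ndarray | None = None,
                         unit_ids: Sequence[int] | None = None) -> ComponentInterpretation:
    """Correlate H rows with known signals; map units to dominant components.

    Known signals must already be sampled/binned on the same time grid as H's
    columns.
    """
    H = factorization.H
    names = tuple(known_signals)
    corr = np.zeros((H.shape[0], len(names)))
    for j, name in enumerate(names):
        sig = np.asarray(known_signals[name], dtype=float)
        if sig.shape[0] != H.shape[1]:
            raise ValueError(
                f"signal {name!r} has length {sig.shape[0]}, expected {H.shape[1]}"
            )
        for i in range(H.shape[0]):
            corr[i, j] = _safe_corr(H[i], sig)
    W = factorization.W
    dominant = np.argmax(W, axis=1)
    magnitude = W[np.arange(W.shape[0]), dominant]
    return ComponentInterpretation(
        signal_names=names,
        correlations=corr,
        dominant_component=dominant,
        dominant_magnitude=magnitude,
        positions=None if positions is None else np.asarray(positions, dtype=float),
        unit_ids=tuple(unit_ids) if unit_ids is not None else None,
    )


def match_components(H_est: np.ndarray, H_true: np.ndarray):
    """Hungarian matching of estimated to planted components by |correlation|.

    Returns (assignment, correlations): ``assignment[i]`` is the planted
    component matched to estimated component i, and ``correlations[i]`` the
    absolute Pearson correlation of the matched pair.  Handles NMF's
    permutation and scale ambiguity when scoring recovery.
    """
    from scipy.optimize import linear_sum_assignment

    H_est = np.asarray(H_est, dtype=float)
    H_true = np.asarray(H_true, dtype=float)
    k = H_est.shape[0]
    cost = np.zeros((k, H_true.shape[0]))
    for i in range(k):
        for j in range(H_true.shape[0]):
            cost[i, j] = -abs(_safe_corr(H_est[i], H_true[j]))
    rows, cols = linear_sum_assignment(cost)
    corrs = -cost[rows, cols]
    return cols, corrs
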