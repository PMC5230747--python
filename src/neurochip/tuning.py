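"""Stimulus tuning curves of single units and their classification.

The stimulus is a per-timestep scalar (for circuit fixtures, the value on the
output bus — the analogue of output-pixel luminance).  A unit's tuning curve
is its mean trailing-window rate at each distinct stimulus value, which is
exactly occupancy normalization: summed activity at a stimulus value divided
by that value's frequency of occurrence.

Classification replaces by-eye judgement with a declared rule: fit a unimodal
Gaussian plus baseline by least squares; call the curve *simple* when the fit
is good (R^2 >= ``r2_threshold``) and its peak lies inside the stimulus
range; *complex* when the fit is poor but the stimulus still explains a
non-trivial share of rate variance (eta^2 >= ``eta2_threshold``); otherwise
*untuned*.  Both thresholds are configuration, not derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["TuningCurve", "StimulusTrace", "tuning_curve", "classify_tuning"]

R2_SIMPLE_DEFAULT = 0.8
ETA2_COMPLEX_DEFAULT = 0.1


@dataclass(frozen=True)
class StimulusTrace:
    """Per-timestep scalar stimulus with a discrete value set."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("stimulus trace must be one-dimensional")
        if not np.isfinite(vals).all():
            raise ValueError("stimulus trace must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class TuningCurve:
    """Mean rate and occupancy per stimulus value, plus derived statistics."""

    stimulus_values: np.ndarray  # sorted distinct values with occupancy > 0
    mean_rate: np.ndarray
    occupancy: np.ndarray  # timestep counts; sums to scored timesteps
    eta_squared: float  # share of rate variance explained by the stimulus
    fit: dict = field(default_factory=dict)

    def as_mapping(self) -> Mapping[float, float]:
        return dict(zip(self.stimulus_values, self.mean_rate))

    @property
    def peak_stimulus(self) -> float:
        return float(self.stimulus_values[int(np.argmax(self.mean_rate))])

    def to_frame(self, unit: int | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "stimulus": self.stimulus_values,
                "occupancy": self.occupancy,
                "mean_rate": self.mean_rate,
            }
        )
        if unit is not None:
            df.insert(0, "unit", unit)
        return df


def tuning_curve(rates: np.ndarray, stimulus: StimulusTrace | np.ndarray) -> TuningCurve:
    """Occupancy-normalized mean rate as a function of stimulus value.

    ``rates`` is one unit's per-timestep rate sequence (trailing-window
    counts).  Values with zero occupancy are absent from the curve.
    """
    if isinstance(stimulus, StimulusTrace):
        stim = stimulus.values
    else:
        stim = np.asarray(stimulus, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n = min(rates.shape[-1], stim.shape[0])
    if n == 0:
        raise ValueError("no overlapping timesteps between rates and stimulus")
    rates = rates[..., :n].reshape(-1)
    stim = stim[:n]
    values, inverse, occupancy = np.unique(stim, return_inverse=True,
                                           return_counts=True)
    sums = np.bincount(inverse, weights=rates, minlength=len(values))
    means = sums / occupancy
    total_var = rates.var()
    if total_var > 0:
        between = np.sum(occupancy * (means - rates.mean()) ** 2) / n
        eta2 = float(between / total_var)
    else:
        eta2 = 0.0
    return TuningCurve(
        stimulus_values=values,
        mean_rate=means,
        occupancy=occupancy,
        eta_squared=eta2,
    )


def _gauss_baseline(s, a, mu, w, b):
    return a * np.exp(-((s - mu) ** 2) / (2.0 * w ** 2)) + b


def fit_unimodal_gaussian(curve: TuningCurve) -> dict:
    """Least-squares Gaussian-plus-baseline fit over the curve's support."""
    s = curve.stimulus_values
    r = curve.mean_rate
    span = float(s.max() - s.min()) or 1.0
    b0 = float(r.min())
    a0 = float(r.max() - r.min()) or 1e-6
    mu0 = float(s[int(np.argmax(r))])
    w0 = span / 4.0
    try:
        popt, _ = curve_fit(
            _gauss_baseline, s, r, p0=(a0, mu0, w0, b0),
            bounds=([0.0, s.min() - span, 1e-6, -np.inf],
                    [np.inf, s.max() + span, 10.0 * span, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return {"converged": False, "r_squared": 0.0}
    resid = r - _gauss_baseline(s, *popt)
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    a, mu, w, b = (float(v) for v in popt)
    return {
        "converged": True,
        "amplitude": a,
        "peak": mu,
        "width": w,
        "baseline": b,
        "r_squared": r2,
        "peak_interior": bool(s.min() <= mu <= s.max()),
    }


def classify_tuning(curve: TuningCurve,
                    r2_threshold: float = R2_SIMPLE_DEFAULT,
                    eta2_threshold: float = ETA2_COMPLEX_DEFAULT) -> str:
    """Deterministic {simple, complex, untuned} label; stores fit in curve.

    Requires >= 4 distinct stimulus values.  Degenerate (zero-variance)
    curves are untuned.  The label is invariant to scaling the rates by any
    positive constant.
    """
    if len(curve.stimulus_values) < 4:
        raise ValueError("classification requires >= 4 distinct stimulus values")
    if curve.mean_rate.var() == 0:
        curve.fit = {"converged": False, "r_squared": 0.0, "class": "untuned"}
        return "untuned"
    fit = fit_unimodal_gaussian(curve)
    if fit.get("converged") and fit["r_squared"] >= r2_threshold and fit.get(
        "peak_interior", False
    ):
        label = "simple"
    elif curve.eta_squared >= eta2_threshold:
        label = "complex"
    else:
        label = "untuned"
    fit["class"] = label
    curve.fit = fit
    return label
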