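"""Implied-timescale analysis and lag-time selection.

A Markov state model is validated by checking that the implied
timescales t_i(τ) = −τ / ln λ_i(τ) become independent of the lag τ; the
smallest lag past which the slowest timescale stops moving (relative
change below a threshold) is selected for production estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..discretize import DiscreteTrajectory, connected_set, count_transitions, restrict
from .msm import estimate_msm_reversible


@dataclass
class ImpliedTimescaleCurve:
    """Implied timescales (ns) per tested lag; NaN where undefined."""

    lags_steps: np.ndarray
    lags_ns: np.ndarray
    timescales: np.ndarray  # (n_lags, n_its)

    def slowest(self) -> np.ndarray:
        return self.timescales[:, 0]


def implied_timescales(
    dtrajs: list[DiscreteTrajectory],
    lags: list[int],
    n_timescales: int = 1,
    mode: str = "sliding",
) -> ImpliedTimescaleCurve:
    """Estimate t_i(τ) from pooled counts at each lag (steps).

    Lags at which the pooled counts are disconnected or the estimator
    fails are reported as NaN rows with a warning rather than aborting
    the scan.
    """
    lags = sorted(int(l) for l in lags)
    if len(lags) < 2:
        raise ValueError("need at least 2 lags to assess convergence")
    dt = dtrajs[0].dt
    ts = np.full((len(lags), n_timescales), np.nan)
    for row, lag in enumerate(lags):
        pooled = sum(count_transitions(d, lag, mode) for d in dtrajs)
        try:
            cs = connected_set(pooled)
            model = estimate_msm_reversible(restrict(pooled, cs), lag_ns=lag * dt)
        except ValueError as exc:
            warnings.warn(f"lag {lag}: {exc}; omitted", stacklevel=2)
            continue
        t = model.timescales()
        m = min(n_timescales, t.size)
        if m == 0 or not np.any(np.isfinite(t[:m])):
            warnings.warn(
                f"lag {lag}: no resolvable timescale (model collapsed to "
                f"{model.n_states} state(s)); omitted",
                stacklevel=2,
            )
            continue
        ts[row, :m] = t[:m]
    return ImpliedTimescaleCurve(
        lags_steps=np.asarray(lags), lags_ns=np.asarray(lags) * dt, timescales=ts
    )


def select_lag(curve: ImpliedTimescaleCurve, threshold: float = 0.05) -> int:
    """Smallest tested lag (steps) whose slowest timescale is converged.

    Lag τ_k is accepted when |t₂(τ_{k+1}) − t₂(τ_k)| / t₂(τ_k) < threshold.
    If no lag satisfies the criterion the largest tested lag is returned
    with a warning.
    """
    t2 = curve.slowest()
    for k in range(len(t2) - 1):
        if np.isnan(t2[k]) or np.isnan(t2[k + 1]):
            continue
        if abs(t2[k + 1] - t2[k]) / abs(t2[k]) < threshold:
            return int(curve.lags_steps[k])
    warnings.warn(
        "no lag met the implied-timescale convergence threshold; "
        "using the largest tested lag",
        stacklevel=2,
    )
    return int(curve.lags_steps[-1])
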