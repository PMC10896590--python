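"""End-to-end estimation pipeline and trajectory-level bootstrap.

Chains discretization → counting → dTRAM → free-energy referencing for a
set of mixed biased/unbiased trajectories, and attaches per-bin bootstrap
errors obtained by resampling whole trajectories with replacement (the
resampling unit respects temporal correlation within a trajectory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..discretize import BinGrid, assign_bins, connected_set, count_tensor, restrict
from ..synthdata.langevin import child_seed
from .dtram import BiasMatrix, DTRAMResult, dtram
from .profile import FreeEnergyProfile, free_energy_from_pi


def bulk_bins(grid: BinGrid, z_from: float, z_to: float | None = None) -> np.ndarray:
    """Global indices of bins whose centers lie in the bulk range [z_from, z_to]."""
    c = grid.centers
    hi = np.inf if z_to is None else z_to
    return np.flatnonzero((c >= z_from) & (c <= hi))


@dataclass
class ProfileEstimate:
    """A free-energy profile plus everything needed to reproduce it."""

    profile: FreeEnergyProfile
    dtram_result: DTRAMResult
    states: np.ndarray          # global bin indices of the connected set
    samples_per_bin: np.ndarray  # frames observed per connected-set bin


def profile_from_trajectories(
    trajs,
    grid: BinGrid,
    lag: int,
    kt: float,
    reference_bins: np.ndarray,
    mode: str = "sliding",
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> ProfileEstimate:
    """Estimate the unbiased free-energy profile from mixed ensembles.

    ``reference_bins`` are global grid indices declaring the unbound/bulk
    plateau; the profile is shifted so their mean free energy is zero.
    """
    dtrajs = [assign_bins(t, grid) for t in trajs]
    counts = count_tensor(dtrajs, grid, lag, mode)
    states = connected_set(counts.pooled())
    C = restrict(counts.counts, states)
    bias = BiasMatrix.from_trajectories(trajs, grid, kt)
    result = dtram(
        C, bias.b[:, states], states=states, lag_ns=counts.lag_ns,
        tol=tol, max_iter=max_iter,
    )
    local_ref = np.flatnonzero(np.isin(states, reference_bins))
    profile = free_energy_from_pi(
        result.pi, kt, grid.centers[states], reference_bins=local_ref
    )
    samples = np.zeros(len(states), dtype=np.int64)
    hist = np.zeros(grid.n_bins, dtype=np.int64)
    for d in dtrajs:
        idx = d.indices[d.indices >= 0]
        hist += np.bincount(idx, minlength=grid.n_bins)
    samples[:] = hist[states]
    return ProfileEstimate(profile=profile, dtram_result=result, states=states,
                           samples_per_bin=samples)


def bootstrap_profile(
    trajs,
    grid: BinGrid,
    lag: int,
    kt: float,
    reference_bins: np.ndarray,
    n_resamples: int = 100,
    seed: int = 0,
    mode: str = "sliding",
    tol: float = 1e-7,
    max_iter: int = 100_000,
    max_dropped_fraction: float = 0.2,
) -> np.ndarray:
    """Per-bin bootstrap SD of the free-energy profile, on the full grid.

    Resamples whole trajectories with replacement ``n_resamples`` times and
    reruns the full pipeline.  Replicates that lose connectivity (or lose
    the reference bins) are dropped and counted; more than
    ``max_dropped_fraction`` dropped aborts.  Bins a replicate does not
    cover contribute nothing to that bin's SD.  Returns an array of length
    ``grid.n_bins`` (NaN where fewer than 2 replicates reported the bin).
    """
    if len(trajs) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    rng_seeds = [child_seed(seed, b) for b in range(n_resamples)]
    values = np.full((n_resamples, grid.n_bins), np.nan)
    dropped = 0
    for b, s in enumerate(rng_seeds):
        rng = np.random.default_rng(s)
        pick = rng.integers(0, len(trajs), size=len(trajs))
        sample = [trajs[i] for i in pick]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = profile_from_trajectories(
                    sample, grid, lag, kt, reference_bins,
                    mode=mode, tol=tol, max_iter=max_iter,
                )
            if not np.any(np.isin(est.states, reference_bins)):
                raise ValueError("replicate lost the reference bins")
        except (ValueError, FloatingPointError):
            dropped += 1
            continue
        values[b, est.states] = est.profile.values
    if dropped > max_dropped_fraction * n_resamples:
        raise RuntimeError(
            f"{dropped}/{n_resamples} bootstrap replicates dropped "
            "(lost connectivity); data too sparse for error bars"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_ok = np.sum(np.isfinite(values), axis=0)
        err = np.nanstd(values, axis=0, ddof=1)
    err[n_ok < 2] = np.nan
    if n_resamples == 1:
        err = np.where(n_ok == 1, 0.0, np.nan)
    return err
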