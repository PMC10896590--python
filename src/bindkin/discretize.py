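"""Discretization of reaction-coordinate trajectories.

Maps 1D trajectories onto a shared bin grid (half-open bins, last bin
closed), builds per-ensemble transition-count matrices at a chosen lag,
and restricts the state space to the largest (reversibly) connected set
— the standard preprocessing behind a Markov state model built on a
binding reaction coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

if TYPE_CHECKING:  # pragma: no cover - avoids a package import cycle
    from .synthdata.langevin import EnsembleTrajectory

#: Bin index used for frames that fall outside the grid.
SENTINEL = -1


@dataclass(frozen=True)
class BinGrid:
    """Strictly increasing bin edges on z (Å).

    Bin i is the half-open interval [edges[i], edges[i+1]); the last bin
    additionally includes its right edge, so the grid tiles
    [edges[0], edges[-1]] exactly.
    """

    edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least 2 edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def from_width(cls, z_min: float, z_max: float, width: float = 0.5) -> "BinGrid":
        """Uniform grid of the given bin width covering [z_min, z_max]."""
        n = int(round((z_max - z_min) / width))
        if n < 1 or not np.isclose(z_min + n * width, z_max):
            n = int(np.ceil((z_max - z_min) / width))
        return cls(z_min + width * np.arange(n + 1))

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def assign(self, z) -> np.ndarray:
        """Map values to bin indices; out-of-grid values get SENTINEL (-1)."""
        z = np.asarray(z, dtype=float)
        idx = np.searchsorted(self.edges, z, side="right") - 1
        idx[z == self.edges[-1]] = self.n_bins - 1  # last bin is closed
        idx[(z < self.edges[0]) | (z > self.edges[-1])] = SENTINEL
        return idx


@dataclass
class DiscreteTrajectory:
    """Bin-index series for one ensemble; SENTINEL marks dropped frames."""

    indices: np.ndarray
    dt: float
    n_bins: int
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        bad = (self.indices >= self.n_bins) | (
            (self.indices < 0) & (self.indices != SENTINEL)
        )
        if bad.any():
            raise ValueError("bin indices out of range")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def n_out_of_grid(self) -> int:
        return int(np.sum(self.indices == SENTINEL))


def assign_bins(traj: EnsembleTrajectory, grid: BinGrid) -> DiscreteTrajectory:
    """Discretize one trajectory.  Out-of-grid frames are kept in place as
    sentinels (never clamped) and reported via ``n_out_of_grid``."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return DiscreteTrajectory(
        grid.assign(traj.z), dt=traj.dt, n_bins=grid.n_bins, label=traj.label
    )


def count_transitions(
    dtraj: DiscreteTrajectory, lag: int, mode: str = "sliding"
) -> np.ndarray:
    """Transition-count matrix C with C[i, j] = #{t: s_t = i, s_{t+lag} = j}.

    ``sliding`` uses every start time t; ``strided`` uses t = 0, lag, 2·lag,…
    Pairs touching a sentinel frame are skipped; counting never crosses
    trajectory boundaries (each call sees a single trajectory).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 step")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"mode must be sliding or strided, got {mode!r}")
    n = dtraj.n_bins
    C = np.zeros((n, n), dtype=np.int64)
    s = dtraj.indices
    if lag >= s.size:
        warnings.warn(
            f"lag {lag} >= trajectory length {s.size}; empty counts", stacklevel=2
        )
        return C
    a, b = s[:-lag], s[lag:]
    if mode == "strided":
        a, b = a[::lag], b[::lag]
    ok = (a != SENTINEL) & (b != SENTINEL)
    np.add.at(C, (a[ok], b[ok]), 1)
    return C


@dataclass
class CountTensor:
    """Per-ensemble count matrices C^k(τ) on a shared grid."""

    counts: np.ndarray  # (K, n, n) int64
    grid: BinGrid
    lag_steps: int
    dt: float
    mode: str = "sliding"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[1] != self.counts.shape[2]:
            raise ValueError("counts must have shape (K, n, n)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not self.labels:
            self.labels = [f"ensemble{k}" for k in range(self.counts.shape[0])]

    @property
    def n_ensembles(self) -> int:
        return self.counts.shape[0]

    @property
    def lag_ns(self) -> float:
        return self.lag_steps * self.dt

    def pooled(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def count_tensor(
    dtrajs: list[DiscreteTrajectory], grid: BinGrid, lag: int, mode: str = "sliding"
) -> CountTensor:
    """Count each discrete trajectory as its own ensemble at the given lag."""
    if not dtrajs:
        raise ValueError("no trajectories")
    dt = dtrajs[0].dt
    counts = np.stack([count_transitions(d, lag, mode) for d in dtrajs])
    return CountTensor(
        counts, grid=grid, lag_steps=lag, dt=dt, mode=mode,
        labels=[d.label for d in dtrajs],
    )


def connected_set(counts: np.ndarray) -> np.ndarray:
    """Largest reversibly connected state set of pooled counts.

    States i, j are linked iff C[i,j] + C[j,i] > 0 (connectivity on the
    symmetrized graph, matching the reversible estimators downstream).
    Among components, the one carrying the most counts wins.
    """
    counts = np.asarray(counts)
    sym = counts + counts.T
    visited = sym.sum(axis=1) > 0
    if not visited.any():
        raise ValueError("no transitions recorded; cannot form a connected set")
    n_comp, labels = connected_components(csr_matrix(sym > 0), directed=False)
    best, best_weight = None, -1
    for c in range(n_comp):
        members = np.flatnonzero((labels == c) & visited)
        if members.size == 0:
            continue
        weight = int(counts[np.ix_(members, members)].sum())
        if weight > best_weight:
            best, best_weight = members, weight
    return best


def restrict(counts: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Restrict a count matrix (or (K,n,n) stack) to the given states."""
    counts = np.asarray(counts)
    if counts.ndim == 2:
        return counts[np.ix_(states, states)]
    return np.stack([c[np.ix_(states, states)] for c in counts])
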