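"""Gaussian coordinate-frame generator with a prescribed covariance.

Produces zero-mean displacement frames whose per-axis population
covariance over pseudo-atoms equals a given PSD matrix, so the dynamic
cross-correlation estimator can be tested against its generating truth.
Frames share one lab frame by construction (no net rotation/translation
is added), so correlation analysis on them needs no superposition.
"""

from __future__ import annotations

import numpy as np

from ..structure import StructureFrame, Trajectory


def make_correlated_frames(
    cov: np.ndarray,
    n_frames: int,
    seed: int,
    base: np.ndarray | None = None,
) -> np.ndarray:
    """Sample frames (n_frames, n_atoms, 3) with per-axis covariance ``cov``.

    Each Cartesian axis receives an independent N(0, cov) draw, so the
    displacement-vector correlation ⟨Δr_i·Δr_j⟩ normalizes to
    cov_ij / sqrt(cov_ii·cov_jj).  ``base`` (n_atoms, 3) offsets the mean
    positions; default is atoms spread 5 Å apart along x.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n) or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be square and symmetric")
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError(f"covariance is not PSD: min eigenvalue {w.min():.3g}")
    L = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal((n_frames, 3, n)) @ L.T  # (F, 3, n)
    disp = disp.transpose(0, 2, 1)                       # (F, n, 3)
    if base is None:
        base = np.zeros((n, 3))
        base[:, 0] = 5.0 * np.arange(n)
    return np.asarray(base, float)[None, :, :] + disp


def frames_to_trajectory(coords: np.ndarray) -> Trajectory:
    """Wrap raw frames as a trajectory of pseudo-Cα residues (GLY chain A)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    topo = StructureFrame(
        names=np.array(["CA"] * n),
        resnames=np.array(["GLY"] * n),
        resids=np.arange(1, n + 1),
        chains=np.array(["A"] * n),
        elements=np.array(["C"] * n),
        coords=coords[0],
    )
    return Trajectory(topology=topo, coords=coords)
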