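"""Discrete transition-based reweighting (dTRAM).

Jointly estimates one unbiased stationary distribution π from the
transition counts of several ensembles — umbrella windows with known
harmonic bias energies plus unbiased runs — by maximizing

    L = ∑_k ∑_ij C^k_ij ln p^k_ij

over per-ensemble transition matrices p^k that are row-stochastic and in
detailed balance with their biased stationary weights
q^k_i ∝ π_i · exp(−b^k_i).

Solver
------
For fixed π the inner problem — the maximum-likelihood reversible
transition matrix with a *prescribed* stationary distribution — has the
well-behaved self-consistent solution

    x^k_ij = (C^k_ij + C^k_ji) · q^k_i q^k_j / (ν^k_i q^k_j + ν^k_j q^k_i)
    ν^k_i  ← ∑_j (C^k_ij + C^k_ji) · ν^k_i q^k_j / (ν^k_i q^k_j + ν^k_j q^k_i)

with p^k_ij = x^k_ij / q^k_i and Lagrange multipliers ν^k_i enforcing the
row sums.  The outer problem is solved by direct quasi-Newton ascent of
the profile likelihood L(π): by the envelope theorem its gradient is

    ∂L/∂ln π_i = ∑_k (ν^k_i − c^k_i),   c^k_i = ∑_j C^k_ij,

so stationarity reproduces the textbook condition ∑_k ν^k_i = ∑_k c^k_i.
With a single unbiased ensemble the optimum coincides exactly with the
reversible MSM estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..discretize import CountTensor
from .msm import TransitionModel, estimate_msm_reversible


@dataclass
class BiasMatrix:
    """Dimensionless (kT) bias energies b^k_i per ensemble k and bin i."""

    b: np.ndarray  # (K, n)

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        if self.b.ndim != 2:
            raise ValueError("bias matrix must be 2D (ensembles x bins)")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("bias energies must be finite")

    @classmethod
    def from_trajectories(cls, trajs, grid, kt: float) -> "BiasMatrix":
        """Evaluate each trajectory's BiasSpec at the bin centers, in kT."""
        b = np.stack([t.bias.energy_kt(grid.centers, kt) for t in trajs])
        return cls(b)


@dataclass
class DTRAMResult:
    """Unbiased stationary distribution and solver diagnostics."""

    pi: np.ndarray          # unbiased stationary distribution on `states`
    states: np.ndarray      # global bin indices of the connected set
    lag_ns: float
    n_iter: int
    increment: float
    converged: bool
    log_likelihood: float
    lagrangians: np.ndarray = field(repr=False, default=None)

    @property
    def f_kt(self) -> np.ndarray:
        """Unbiased bin free energies −ln π in kT (unreferenced)."""
        return -np.log(self.pi)


def _pool_identical_biases(C: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum count matrices of ensembles whose bias rows are identical."""
    # constant offsets within a row are a gauge choice, so compare shifted rows
    Bs = B - B.min(axis=1, keepdims=True)
    _, inverse = np.unique(np.round(Bs, 12), axis=0, return_inverse=True)
    n_states = int(inverse.max()) + 1
    if n_states == C.shape[0]:
        return C, B
    Cp = np.zeros((n_states,) + C.shape[1:], dtype=C.dtype)
    Bp = np.zeros((n_states, B.shape[1]))
    for k, g in enumerate(inverse):
        Cp[g] += C[k]
        Bp[g] = Bs[k]
    return Cp, Bp


class _InnerState:
    """Per-ensemble reversible-MLE-at-fixed-π solver with warm starts.

    Works on the flattened nonzero entries of the symmetrized count tensor
    (transitions are banded along a 1D coordinate, so the tensor is very
    sparse) with bincount row reductions.
    """

    def __init__(self, C: np.ndarray, Bshift: np.ndarray):
        K, n, _ = C.shape
        self.K, self.n = K, n
        self.crow = C.sum(axis=2)
        self.expB = np.exp(-Bshift)
        Csym = C + C.transpose(0, 2, 1)
        k_idx, i_idx, j_idx = np.nonzero(Csym)
        self.i_idx, self.j_idx, self.k_idx = i_idx, j_idx, k_idx
        self.fi = k_idx * n + i_idx
        self.fj = k_idx * n + j_idx
        self.Cs_v = Csym[k_idx, i_idx, j_idx].astype(float)
        self.C_v = C[k_idx, i_idx, j_idx].astype(float)
        self.nu = self.crow.astype(float).ravel().copy()

    def solve(self, pi: np.ndarray, tol: float = 1e-12, max_sweeps: int = 500) -> int:
        """Converge ν for fixed π; returns the number of sweeps used."""
        q = (pi[None, :] * self.expB).ravel()
        qi, qj = q[self.fi], q[self.fj]
        nu = self.nu
        scale = np.maximum(self.crow.ravel(), 1.0)
        for sweep in range(1, max_sweeps + 1):
            nui, nuj = nu[self.fi], nu[self.fj]
            r = self.Cs_v * nui * qj / (nui * qj + nuj * qi)
            nu_new = np.bincount(self.fi, weights=r, minlength=self.K * self.n)
            delta = np.max(np.abs(nu_new - nu) / scale)
            nu = nu_new
            if delta < tol:
                break
        self.nu = nu
        return sweep

    def _p_values(self, pi: np.ndarray) -> np.ndarray:
        """p^k_ij on the nonzero entries, using the current ν."""
        q = (pi[None, :] * self.expB).ravel()
        qi, qj = q[self.fi], q[self.fj]
        nui, nuj = self.nu[self.fi], self.nu[self.fj]
        x = self.Cs_v * qi * qj / (nui * qj + nuj * qi)
        return x / qi

    def log_likelihood(self, pi: np.ndarray) -> float:
        p = self._p_values(pi)
        m = self.C_v > 0
        if np.any(~np.isfinite(p[m])) or np.any(p[m] <= 0):
            return -np.inf
        return float(np.sum(self.C_v[m] * np.log(p[m])))

    def gradient_logpi(self) -> np.ndarray:
        """∂L/∂ln π_i = Σ_k (ν^k_i − c^k_i) at the inner optimum."""
        return (self.nu.reshape(self.K, self.n) - self.crow).sum(axis=0)

    def transition_matrices(self, pi: np.ndarray) -> np.ndarray:
        p = np.zeros((self.K, self.n, self.n))
        p[self.k_idx, self.i_idx, self.j_idx] = self._p_values(pi)
        return p


def dtram(
    counts: CountTensor | np.ndarray,
    bias: BiasMatrix | np.ndarray,
    states: np.ndarray | None = None,
    lag_ns: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    init_pi: np.ndarray | None = None,
) -> DTRAMResult:
    """Estimate the unbiased stationary distribution from mixed ensembles.

    ``counts``/``bias`` must already be restricted to the global connected
    set (states with pooled counts).  Ensembles with no counts at all are
    excluded with a warning.  ``tol`` bounds the gradient of the profile
    log-likelihood per observed transition; non-convergence returns with
    ``converged=False`` and the residual.
    """
    if isinstance(counts, CountTensor):
        lag_ns = counts.lag_ns if lag_ns is None else lag_ns
        C = np.asarray(counts.counts, dtype=float)
    else:
        C = np.asarray(counts, dtype=float)
    if lag_ns is None:
        raise ValueError("lag_ns required when counts is a raw array")
    B = bias.b if isinstance(bias, BiasMatrix) else np.asarray(bias, dtype=float)
    K, n, _ = C.shape
    if B.shape != (K, n):
        raise ValueError(f"bias shape {B.shape} does not match counts {(K, n)}")

    keep = C.reshape(K, -1).sum(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} ensemble(s) with zero counts",
            stacklevel=2,
        )
        C, B = C[keep], B[keep]
        K = C.shape[0]
    if K == 0:
        raise ValueError("no ensembles with counts")
    # ensembles are thermodynamic states: trajectories sharing one bias
    # vector (e.g. several unbiased runs) pool their counts
    C, B = _pool_identical_biases(C, B)
    K = C.shape[0]
    pooled_sym = (C + C.transpose(0, 2, 1)).sum(axis=0)
    if np.any(pooled_sym.sum(axis=1) == 0):
        raise ValueError("states without any transitions; restrict to the connected set")

    # gauge: shift each ensemble's bias by its own minimum (likelihood-invariant)
    Bshift = B - B.min(axis=1, keepdims=True)
    inner = _InnerState(C, Bshift)
    total_counts = C.sum()

    if init_pi is None:
        # histogram-style init: pooled reweighted visit counts
        visits = inner.crow + C.sum(axis=1)  # in + out counts per ensemble
        with np.errstate(divide="ignore"):
            est = (visits * np.exp(Bshift)).sum(axis=0)
        est = np.where(est > 0, est, est[est > 0].min())
        y0 = np.log(est / est.sum())
    else:
        y0 = np.log(np.asarray(init_pi, float))

    n_eval = 0

    def objective(y):
        nonlocal n_eval
        n_eval += 1
        logpi = y - np.max(y)
        pi = np.exp(logpi)
        pi /= pi.sum()
        inner.solve(pi)
        ll = inner.log_likelihood(pi)
        g = inner.gradient_logpi()
        # chain rule through the normalization of pi
        grad_y = g - pi * g.sum()
        return -ll / total_counts, -grad_y / total_counts

    y = y0
    residual = np.inf
    for _attempt in range(3):
        res = minimize(
            objective,
            y,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": tol / 10.0},
        )
        y = res.x
        pi = np.exp(y - np.max(y))
        pi /= pi.sum()
        inner.solve(pi)
        grad = inner.gradient_logpi()
        residual = float(np.max(np.abs(grad)) / total_counts)
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        warnings.warn(
            f"dTRAM optimizer stopped after {n_eval} evaluations with "
            f"gradient residual {residual:.3g} (tol {tol:.3g})",
            stacklevel=2,
        )
    return DTRAMResult(
        pi=pi,
        states=np.arange(n) if states is None else np.asarray(states, int),
        lag_ns=lag_ns,
        n_iter=n_eval,
        increment=residual,
        converged=converged,
        log_likelihood=inner.log_likelihood(pi),
        lagrangians=inner.nu,
    )


def ensemble_transition_matrices(
    result: DTRAMResult, counts: CountTensor, bias: BiasMatrix
) -> list[TransitionModel | None]:
    """Per-ensemble reversible transition matrices implied by dTRAM.

    Each ensemble's matrix lives on its own connected sub-set of bins (an
    umbrella window only visits bins near its center); ensembles whose
    counts cannot support a model return None.
    """
    from ..discretize import connected_set, restrict

    out: list[TransitionModel | None] = []
    for k in range(counts.n_ensembles):
        Ck = counts.counts[k]
        try:
            sub = connected_set(Ck)
            model = estimate_msm_reversible(
                restrict(Ck, sub), lag_ns=counts.lag_ns, states=result.states[sub]
            )
        except ValueError:
            model = None
        out.append(model)
    return out
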