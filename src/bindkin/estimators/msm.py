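"""Maximum-likelihood reversible Markov state models.

Estimates the row-stochastic transition matrix T(τ) maximizing
∏_ij T_ij^{C_ij} subject to detailed balance π_i T_ij = π_j T_ji, via the
classic self-consistent fixed-point iteration on the symmetric flux
variables x_ij = π_i T_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class TransitionModel:
    """A reversible transition matrix with its stationary distribution.

    ``states`` records which global bin indices the model lives on (the
    connected set); ``eigenvalues`` are sorted descending and real because
    the matrix is reversible.
    """

    T: np.ndarray
    pi: np.ndarray
    lag_ns: float
    states: np.ndarray = field(default=None)
    eigenvalues: np.ndarray = field(default=None)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.T.shape[0]
        if self.T.shape != (n, n) or self.pi.shape != (n,):
            raise ValueError("inconsistent shapes")
        if self.states is None:
            self.states = np.arange(n)
        self.states = np.asarray(self.states, dtype=int)
        if self.eigenvalues is None:
            self.eigenvalues = reversible_eigenvalues(self.T, self.pi)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def validate(self, rtol_rows: float = 1e-10, rtol_db: float = 1e-8) -> None:
        """Assert row-stochasticity, stationarity and detailed balance."""
        if np.max(np.abs(self.T.sum(axis=1) - 1.0)) > rtol_rows:
            raise ValueError("rows do not sum to 1")
        if np.max(np.abs(self.pi @ self.T - self.pi)) > rtol_db:
            raise ValueError("pi is not stationary")
        flux = self.pi[:, None] * self.T
        if np.max(np.abs(flux - flux.T)) > rtol_db:
            raise ValueError("detailed balance violated")

    def timescales(self) -> np.ndarray:
        """Implied timescales t_i = −τ / ln λ_i for i ≥ 2, in ns.

        Only real eigenvalues in (0, 1) yield finite timescales; others
        come back as NaN.
        """
        lam = self.eigenvalues[1:]
        ts = np.full(lam.shape, np.nan)
        ok = (lam > 0) & (lam < 1)
        ts[ok] = -self.lag_ns / np.log(lam[ok])
        return ts


def reversible_eigenvalues(T: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Eigenvalues of a reversible T via the π-symmetrized similar matrix."""
    s = np.sqrt(pi)
    sym = (s[:, None] * T) / s[None, :]
    lam = np.linalg.eigvalsh(0.5 * (sym + sym.T))
    return lam[::-1]


def second_right_eigenvector(T: np.ndarray, pi: np.ndarray) -> tuple[float, np.ndarray]:
    """(λ₂, ψ₂): the slowest non-stationary mode of a reversible T."""
    s = np.sqrt(pi)
    sym = (s[:, None] * T) / s[None, :]
    lam, vec = np.linalg.eigh(0.5 * (sym + sym.T))
    return float(lam[-2]), vec[:, -2] / s


def log_likelihood(T: np.ndarray, counts: np.ndarray) -> float:
    """∑_ij C_ij ln T_ij over pairs with C_ij > 0."""
    mask = counts > 0
    if np.any(T[mask] <= 0):
        return -np.inf
    return float(np.sum(counts[mask] * np.log(T[mask])))


def estimate_msm_reversible(
    counts: np.ndarray,
    lag_ns: float,
    states: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> TransitionModel:
    """Reversible MLE transition matrix from a (connected) count matrix.

    Fixed point: x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j) with
    x_i = Σ_j x_ij, converged when the stationary distribution changes by
    less than ``tol`` in max norm.
    """
    C = np.asarray(counts, dtype=float)
    n = C.shape[0]
    c = C.sum(axis=1)
    if np.any(c == 0):
        raise ValueError("count matrix has an all-zero row; restrict to the connected set first")
    Csym = C + C.T
    x = Csym / Csym.sum()
    pi = x.sum(axis=1)
    delta = np.inf
    for it in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = c[:, None] / pi[:, None] + c[None, :] / pi[None, :]
            x = np.where(Csym > 0, Csym / denom, 0.0)
        x /= x.sum()
        pi_new = x.sum(axis=1)
        delta = float(np.max(np.abs(pi_new - pi)))
        pi = pi_new
        if delta < tol:
            break
    else:
        warnings.warn(
            f"reversible MSM not converged after {max_iter} iterations "
            f"(residual {delta:.3g})",
            stacklevel=2,
        )
    T = x / pi[:, None]
    # clean tiny numerical asymmetries before validation
    T = T / T.sum(axis=1, keepdims=True)
    return TransitionModel(T=T, pi=pi / pi.sum(), lag_ns=lag_ns, states=states)
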