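"""Analytic ground truths for the synthetic potentials.

These quadrature-converged results are what the statistical estimators
are tested against:

- the exact per-bin free energy F_i = −kT·ln ∫_bin e^{−U/kT} dz, and
- the exact 1D overdamped mean first-passage time

      T(a→b) = (1/D) ∫_a^b e^{βU(y)} [ ∫_refl^y e^{−βU(x)} dx ] dy

  with a reflecting boundary on the far side of the start.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

from .potentials import Potential

if TYPE_CHECKING:  # pragma: no cover - avoids a package import cycle
    from ..discretize import BinGrid
    from ..estimators.profile import FreeEnergyProfile

_PTS_PER_BIN = 65
_MFPT_PTS = 8001


def analytic_free_energy(
    pot: Potential,
    grid: BinGrid,
    kt: float,
    reference_bins=None,
) -> FreeEnergyProfile:
    """Exact bin free energies (kcal/mol) of the Boltzmann law on ``pot``.

    The same reference convention as the estimators applies: mean F over
    ``reference_bins`` is zero (falling back to max-F = 0 when empty).
    """
    from ..estimators.profile import FreeEnergyProfile, reference_shift

    lo, hi = pot.domain
    if grid.edges[0] < lo - 1e-9 or grid.edges[-1] > hi + 1e-9:
        raise ValueError("grid extends outside the potential domain")
    log_w = np.empty(grid.n_bins)
    for i in range(grid.n_bins):
        z = np.linspace(grid.edges[i], grid.edges[i + 1], _PTS_PER_BIN)
        u = pot.energy(z)  # kT units
        u0 = u.min()
        log_w[i] = -u0 + np.log(simpson(np.exp(-(u - u0)), x=z))
    values, tag = reference_shift(-kt * log_w, reference_bins)
    return FreeEnergyProfile(
        centers=grid.centers, values=values, kt=kt, reference=tag
    )


def analytic_mfpt(pot: Potential, a: float, b: float, diffusion: float) -> float:
    """Mean first-passage time (ns) from a to b on the 1D potential.

    The reflecting wall sits at the domain end on the far side of ``a``;
    ``b`` is treated as absorbing.  ``a == b`` returns 0.  For a > b the
    coordinate is mirrored so the same double integral applies.
    """
    lo, hi = pot.domain
    if not (lo <= a <= hi and lo <= b <= hi):
        raise ValueError(f"a={a}, b={b} must lie in the domain {pot.domain}")
    if a == b:
        return 0.0
    if a > b:
        # mirror: U'(z) = U(lo + hi - z); reflecting wall lands at -hi → hi
        mirrored = _Mirrored(pot)
        return analytic_mfpt_grid(mirrored, lo + hi - a, lo + hi - b, diffusion, lo)
    return analytic_mfpt_grid(pot, a, b, diffusion, lo)


class _Mirrored:
    """View of a potential with z → lo + hi − z (keeps the same domain)."""

    def __init__(self, pot: Potential):
        self._pot = pot
        self.domain = pot.domain

    def energy(self, z):
        lo, hi = self.domain
        return self._pot.energy(lo + hi - np.asarray(z, float))


def analytic_mfpt_grid(pot, a: float, b: float, diffusion: float, refl: float) -> float:
    """Double integral on a dense Simpson grid from the reflecting wall to b.

    The grid is built from two segments meeting exactly at ``a`` so the
    outer integral's lower limit needs no interpolation.
    """
    n_lower = max(9, int(_MFPT_PTS * (a - refl) / max(b - refl, 1e-12)) | 1)
    z = np.unique(np.concatenate([
        np.linspace(refl, a, n_lower),
        np.linspace(a, b, _MFPT_PTS),
    ]))
    u = pot.energy(z)
    u0 = float(np.median(u))  # scale anchor; cancels between the two factors
    inner = cumulative_simpson(np.exp(-(u - u0)), x=z, initial=0.0)
    integrand = np.exp(u - u0) * inner
    sel = z >= a
    return float(simpson(integrand[sel], x=z[sel]) / diffusion)
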