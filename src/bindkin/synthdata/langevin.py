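"""Overdamped Langevin (Brownian) dynamics on 1D model potentials.

This is the synthetic stand-in for the molecular-dynamics engine: it
produces reaction-coordinate time series with the statistical structure
the downstream estimators assume — Boltzmann-distributed unbiased
ensembles and harmonically restrained (umbrella-window) ensembles.

Update rule (Euler–Maruyama, potential already in kT units):

    z_{t+1} = z_t + D·f(z_t)·dt + sqrt(2·D·dt)·ξ_t,   ξ_t ~ N(0, 1)

with f = -d(βU_eff)/dz and U_eff = U + bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from ..units import DEFAULT_KT
from .potentials import Potential


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella restraint b(z) = 0.5·k_umb·(z − center)², or none.

    ``center`` in Å, ``k_umb`` in kcal/mol/Å².  The distinguished unbiased
    value has ``center=None, k_umb=0``.
    """

    center: float | None = None
    k_umb: float = 0.0

    def __post_init__(self):
        if self.k_umb < 0:
            raise ValueError(f"force constant must be >= 0, got {self.k_umb}")
        if self.center is None and self.k_umb != 0.0:
            raise ValueError("a bias with k_umb > 0 needs a center")

    @property
    def is_biased(self) -> bool:
        return self.center is not None and self.k_umb > 0

    def energy_kcal(self, z):
        """Bias energy in kcal/mol."""
        z = np.asarray(z, dtype=float)
        if not self.is_biased:
            return np.zeros_like(z)
        return 0.5 * self.k_umb * (z - self.center) ** 2

    def energy_kt(self, z, kt: float = DEFAULT_KT):
        """Bias energy in kT units at thermal energy ``kt`` (kcal/mol)."""
        return self.energy_kcal(z) / kt


UNBIASED = BiasSpec()


@dataclass(frozen=True)
class LangevinParams:
    """Integrator parameters: D in Å²/ns, kT in kcal/mol, dt in ns."""

    diffusion: float
    dt: float
    n_steps: int
    seed: int
    initial_z: float
    kt: float = DEFAULT_KT

    def __post_init__(self):
        if self.diffusion <= 0 or self.kt <= 0 or self.dt <= 0:
            raise ValueError("diffusion, kt and dt must all be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class EnsembleTrajectory:
    """A reaction-coordinate time series tagged with its sampling bias."""

    z: np.ndarray
    dt: float
    bias: BiasSpec = UNBIASED
    label: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1 or self.z.size < 2:
            raise ValueError("trajectory needs at least 2 frames")

    def __len__(self) -> int:
        return self.z.size

    @property
    def time_ns(self) -> np.ndarray:
        return np.arange(self.z.size) * self.dt


def _check_stability(pot: Potential, bias: BiasSpec, par: LangevinParams) -> None:
    lo, hi = pot.domain
    span = hi - lo
    if bias.is_biased:
        # a restrained walker samples only its window; check forces there
        sigma = math.sqrt(par.kt / bias.k_umb)
        lo = max(lo, bias.center - max(6.0 * sigma, 2.0))
        hi = min(hi, bias.center + max(6.0 * sigma, 2.0))
    z = np.linspace(lo, hi, 801)
    f = pot.force(z)
    if bias.is_biased:
        f = f - bias.k_umb * (z - bias.center) / par.kt
    fmax = float(np.max(np.abs(f)))
    if par.dt * par.diffusion * fmax**2 >= span:
        warnings.warn(
            f"Euler-Maruyama step may be unstable: dt*D*max|f|^2 = "
            f"{par.dt * par.diffusion * fmax**2:.3g} >= domain span {span:.3g}",
            RuntimeWarning,
            stacklevel=3,
        )


def _reflect(z: float, lo: float, hi: float) -> float:
    # fold back into [lo, hi]; loop handles rare multi-span excursions
    while z < lo or z > hi:
        if z < lo:
            z = 2.0 * lo - z
        else:
            z = 2.0 * hi - z
    return z


def simulate_langevin(
    pot: Potential, par: LangevinParams, bias: BiasSpec = UNBIASED
) -> EnsembleTrajectory:
    """Integrate one trajectory; reproducible given ``par.seed``.

    Reflecting ends fold excursions back into the domain; an absorbing end
    terminates the trajectory at the first crossing (the returned series is
    then shorter than requested).
    """
    lo, hi = pot.domain
    if not (lo <= par.initial_z <= hi):
        raise ValueError(f"initial_z {par.initial_z} outside domain {pot.domain}")
    _check_stability(pot, bias, par)

    force = pot.scalar_force()
    if bias.is_biased:
        kb = bias.k_umb / par.kt
        z0 = bias.center
        base = force
        force = lambda z: base(z) - kb * (z - z0)  # noqa: E731

    rng = np.random.default_rng(par.seed)
    noise = rng.standard_normal(par.n_steps) * math.sqrt(2.0 * par.diffusion * par.dt)
    drift = par.diffusion * par.dt
    absorb_lo = pot.boundary[0] == "absorbing"
    absorb_hi = pot.boundary[1] == "absorbing"

    out = np.empty(par.n_steps + 1)
    out[0] = z = par.initial_z
    n = par.n_steps
    for i in range(par.n_steps):
        f = force(z)
        if not math.isfinite(f):
            raise FloatingPointError(f"non-finite force at z = {z!r} (step {i})")
        z = z + drift * f + noise[i]
        if z < lo:
            if absorb_lo:
                n = i + 1
                out[n] = lo
                break
            z = _reflect(z, lo, hi)
        elif z > hi:
            if absorb_hi:
                n = i + 1
                out[n] = hi
                break
            z = _reflect(z, lo, hi)
        out[i + 1] = z

    label = "unbiased" if not bias.is_biased else f"umbrella(z0={bias.center:g})"
    return EnsembleTrajectory(out[: n + 1], dt=par.dt, bias=bias, label=label, seed=par.seed)


def child_seed(parent: int, index: int) -> int:
    """Deterministic child seed for window ``index`` of a parent seed."""
    return int(np.random.SeedSequence([int(parent), int(index)]).generate_state(1)[0] % 2**31)


def make_umbrella_set(
    pot: Potential,
    centers,
    k_umb: float,
    par: LangevinParams,
) -> list[EnsembleTrajectory]:
    """One umbrella-window trajectory per center, initialized at its center.

    Window seeds derive deterministically from ``par.seed`` (recorded on
    each trajectory), so the whole set is a pure function of its inputs.
    """
    centers = list(centers)
    if not centers:
        raise ValueError("centers list is empty")
    lo, hi = pot.domain
    for c in centers:
        if not (lo <= c <= hi):
            raise ValueError(f"umbrella center {c} outside domain {pot.domain}")
    out = []
    for i, c in enumerate(centers):
        p = replace(par, seed=child_seed(par.seed, i), initial_z=float(c))
        out.append(simulate_langevin(pot, p, BiasSpec(center=float(c), k_umb=k_umb)))
    return out


def first_passage_times(
    pot: Potential,
    par: LangevinParams,
    start: float,
    target: float,
    n_replicas: int,
    max_steps: int | None = None,
) -> np.ndarray:
    """Direct first-passage sampling: times (ns) for ``n_replicas`` walkers
    started at ``start`` to first cross ``target``.

    The boundary on the far side of ``start`` is reflecting; the target
    side is absorbing at ``target``.  Replicas still alive after
    ``max_steps`` (default ``par.n_steps``) raise, since censored samples
    would bias the mean.
    """
    lo, hi = pot.domain
    max_steps = max_steps or par.n_steps
    rightward = target > start
    rng = np.random.default_rng(par.seed)
    sigma = math.sqrt(2.0 * par.diffusion * par.dt)
    drift = par.diffusion * par.dt

    z = np.full(n_replicas, float(start))
    t = np.zeros(n_replicas)
    alive = np.ones(n_replicas, dtype=bool)
    for step in range(1, max_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        f = pot.force(z[idx])
        zn = z[idx] + drift * f + rng.standard_normal(idx.size) * sigma
        # reflect at the far-side wall
        if rightward:
            zn = np.where(zn < lo, 2 * lo - zn, zn)
            hit = zn >= target
        else:
            zn = np.where(zn > hi, 2 * hi - zn, zn)
            hit = zn <= target
        z[idx] = zn
        done = idx[hit]
        t[done] = step * par.dt
        alive[done] = False
    if alive.any():
        raise RuntimeError(
            f"{int(alive.sum())}/{n_replicas} replicas not absorbed within "
            f"{max_steps} steps; increase max_steps"
        )
    return t
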