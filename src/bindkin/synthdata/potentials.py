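"""Analytic 1D potentials U(z) used as model free-energy landscapes.

Potentials are dimensionless (expressed in units of kT) so that the
Langevin dynamics and the analytic free-energy/MFPT oracles never need a
temperature; conversion to kcal/mol happens only when profiles are
reported.  Positions are in Å.

The ``binding_funnel`` kind mimics the shape of a ligand-binding
free-energy profile along a pore-axis separation coordinate: a single
deep bound well plus a small barrier separating it from a flat
bulk/unbound tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

KINDS = ("flat", "harmonic", "double_well", "binding_funnel", "piecewise_linear")
BOUNDARIES = ("reflecting", "absorbing")


@dataclass(frozen=True)
class Potential:
    """An analytic potential on a closed interval of the reaction coordinate.

    Parameters
    ----------
    kind:
        One of ``flat``, ``harmonic``, ``double_well``, ``binding_funnel``,
        ``piecewise_linear``.
    params:
        Kind-specific coefficients (energies in kT, positions/widths in Å):

        - ``harmonic``: ``k`` (kT/Å²), ``center`` (Å)
        - ``double_well`` / ``binding_funnel``: ``wells`` — sequence of
          ``(position, depth_kT, width)`` Gaussian wells — and optional
          ``bumps`` — sequence of ``(position, height_kT, width)`` Gaussian
          barriers.  A funnel must have exactly one interior minimum and a
          flat tail.
        - ``piecewise_linear``: ``points`` — sequence of ``(z, U_kT)`` nodes.
    domain:
        Closed interval ``(z_min, z_max)`` in Å.
    boundary:
        Per-end boundary condition, each ``reflecting`` or ``absorbing``.
    """

    kind: str
    params: Mapping = field(default_factory=dict)
    domain: tuple[float, float] = (0.0, 10.0)
    boundary: tuple[str, str] = ("reflecting", "reflecting")

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown potential kind {self.kind!r}; known: {KINDS}")
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
            raise ValueError(f"domain must be a nonempty finite interval, got {self.domain}")
        for b in self.boundary:
            if b not in BOUNDARIES:
                raise ValueError(f"boundary must be one of {BOUNDARIES}, got {b!r}")
        z = np.linspace(lo, hi, 2001)
        u = self.energy(z)
        if not np.all(np.isfinite(u)):
            raise ValueError("potential is not finite everywhere on its domain")
        if self.kind == "binding_funnel":
            self._check_funnel(z, u)

    def _check_funnel(self, z: np.ndarray, u: np.ndarray) -> None:
        du = np.diff(u)
        sign = np.sign(du[np.abs(du) > 1e-12])
        # interior minima = down-to-up sign changes of the gradient
        n_min = int(np.sum((sign[:-1] < 0) & (sign[1:] > 0)))
        if n_min != 1:
            raise ValueError(
                f"binding_funnel must have exactly one interior minimum, found {n_min}"
            )
        tail = u[z >= z[-1] - 0.15 * (z[-1] - z[0])]
        if np.ptp(tail) > 0.2:
            raise ValueError("binding_funnel must end in a flat bulk tail")

    # ------------------------------------------------------------------
    def energy(self, z):
        """U(z) in kT; accepts scalars or arrays."""
        z = np.asarray(z, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(z)
        if self.kind == "harmonic":
            k = float(self.params["k"])
            c = float(self.params.get("center", 0.0))
            return 0.5 * k * (z - c) ** 2
        if self.kind in ("double_well", "binding_funnel"):
            u = np.zeros_like(z)
            for z0, depth, width in self.params.get("wells", ()):
                u = u - depth * np.exp(-0.5 * ((z - z0) / width) ** 2)
            for z0, height, width in self.params.get("bumps", ()):
                u = u + height * np.exp(-0.5 * ((z - z0) / width) ** 2)
            return u
        if self.kind == "piecewise_linear":
            pts = sorted(self.params["points"])
            xs = np.array([p[0] for p in pts], dtype=float)
            ys = np.array([p[1] for p in pts], dtype=float)
            return np.interp(z, xs, ys)
        raise AssertionError(self.kind)

    def force(self, z):
        """-dU/dz in kT/Å; accepts scalars or arrays."""
        z = np.asarray(z, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(z)
        if self.kind == "harmonic":
            k = float(self.params["k"])
            c = float(self.params.get("center", 0.0))
            return -k * (z - c)
        if self.kind in ("double_well", "binding_funnel"):
            f = np.zeros_like(z)
            for z0, depth, width in self.params.get("wells", ()):
                f = f - depth * (z - z0) / width**2 * np.exp(-0.5 * ((z - z0) / width) ** 2)
            for z0, height, width in self.params.get("bumps", ()):
                f = f + height * (z - z0) / width**2 * np.exp(-0.5 * ((z - z0) / width) ** 2)
            return f
        if self.kind == "piecewise_linear":
            pts = sorted(self.params["points"])
            xs = np.array([p[0] for p in pts], dtype=float)
            ys = np.array([p[1] for p in pts], dtype=float)
            slopes = np.diff(ys) / np.diff(xs)
            idx = np.clip(np.searchsorted(xs, z, side="right") - 1, 0, len(slopes) - 1)
            return -slopes[idx]
        raise AssertionError(self.kind)

    def scalar_force(self) -> Callable[[float], float]:
        """A fast pure-Python force closure for the sequential integrator."""
        if self.kind == "flat":
            return lambda z: 0.0
        if self.kind == "harmonic":
            k = float(self.params["k"])
            c = float(self.params.get("center", 0.0))
            return lambda z: -k * (z - c)
        if self.kind in ("double_well", "binding_funnel"):
            terms = [(z0, -d / w**2, w) for z0, d, w in self.params.get("wells", ())]
            terms += [(z0, h / w**2, w) for z0, h, w in self.params.get("bumps", ())]
            exp = math.exp

            def f(z: float) -> float:
                tot = 0.0
                for z0, a, w in terms:
                    dz = z - z0
                    tot += a * dz * exp(-0.5 * (dz / w) ** 2)
                return tot

            return f
        # piecewise_linear (and any future kind): fall back to the array path
        return lambda z: float(self.force(z))


# ----------------------------------------------------------------------
# Shipped presets.  These fix the study conditions used throughout the
# test suite and the reproduction script; see docs/methods.md.
# ----------------------------------------------------------------------

def preset(name: str) -> Potential:
    """Return a shipped potential preset by name.

    - ``morphinelike``: binding funnel with the bound well at z = 10 Å
      (8 kT deep) and a ~1 kT barrier near z = 22.5 Å before a flat bulk
      tail — the geometry of a deep agonist-binding profile.
    - ``shallow_funnel``: funnel with a 4 kT total escape barrier (2.5 kT
      well at z = 10 Å plus a 1.5 kT barrier bump at z = 16 Å), sized so
      that unbiased trajectories cross the barrier many times.
    - ``double_well_8kT``: asymmetric double well (8 kT and 4 kT deep,
      barrier at the 0 kT baseline), the umbrella-sampling workhorse.
    - ``flat20``: flat potential on [0, 20] Å.
    """
    presets = {
        "morphinelike": Potential(
            "binding_funnel",
            {"wells": [(10.0, 8.0, 1.8)], "bumps": [(22.5, 1.0, 1.5)]},
            domain=(4.0, 32.0),
        ),
        "shallow_funnel": Potential(
            "binding_funnel",
            {"wells": [(10.0, 2.5, 1.2)], "bumps": [(16.0, 1.5, 1.0)]},
            domain=(5.0, 25.0),
        ),
        "double_well_8kT": Potential(
            "double_well",
            {"wells": [(5.0, 8.0, 1.2), (15.0, 4.0, 1.2)]},
            domain=(0.0, 20.0),
        ),
        "flat20": Potential("flat", domain=(0.0, 20.0)),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
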