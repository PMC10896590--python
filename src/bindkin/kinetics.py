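"""Binding kinetics from the Markov state model.

Coarse-grains the validated MSM into bound and unbound metastable states
and computes the mean binding time t_in = MFPT(unbound→bound), the drug
residence time t_out = MFPT(bound→unbound) = 1/k_off, and the
association rate constant k_on = 1/(t_in·C) at a stated ligand
concentration C.  Also ships, as input data, published kinetic
parameters for morphine enantiomers binding the μ-opioid receptor under
four protonation states of the binding-site aspartates, used for
arithmetic consistency checks of exactly these relations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimators.msm import TransitionModel, second_right_eigenvector
from .estimators.pipeline import bulk_bins, profile_from_trajectories
from .estimators.profile import FreeEnergyProfile
from .discretize import BinGrid, assign_bins, connected_set, count_transitions, restrict
from .estimators.msm import estimate_msm_reversible
from .synthdata.langevin import child_seed
from .units import DEFAULT_CONCENTRATION_MM, format_time_ns


@dataclass
class TwoStatePartition:
    """Bound/unbound split of the connected set (local state indices)."""

    bound: np.ndarray
    unbound: np.ndarray
    method: str                 # eigenvector-sign | barrier-split
    barrier_index: int          # local index of the barrier bin
    barrier_z: float | None = None

    def __post_init__(self):
        self.bound = np.asarray(self.bound, dtype=int)
        self.unbound = np.asarray(self.unbound, dtype=int)
        if self.bound.size == 0 or self.unbound.size == 0:
            raise ValueError("both metastable sets must be nonempty")
        if np.intersect1d(self.bound, self.unbound).size:
            raise ValueError("bound and unbound sets overlap")


def _barrier_between(values: np.ndarray, i: int, j: int) -> int:
    lo, hi = (i, j) if i < j else (j, i)
    if hi - lo < 2:
        return hi
    seg = values[lo + 1 : hi]
    return lo + 1 + int(np.nanargmax(seg))


def _barrier_split(profile_values: np.ndarray, bulk=None) -> tuple[int, int]:
    """(barrier bin, global-minimum bin) from a 1D free-energy profile.

    With a declared bulk region the barrier is the highest bin between the
    global minimum and that region.  Otherwise the partner minimum is the
    local minimum with the largest barrier prominence relative to the
    global one — a plain "second-deepest minimum" rule is fooled by noise
    wiggles on a flat plateau.
    """
    v = np.asarray(profile_values, dtype=float)
    n = v.size
    gmin = int(np.nanargmin(v))
    if bulk is not None and len(bulk) > 0:
        other = int(round(float(np.mean(bulk))))
        if other == gmin:
            other = int(bulk[-1])
    else:
        minima = [i for i in range(n)
                  if (i == 0 or v[i] <= v[i - 1]) and (i == n - 1 or v[i] <= v[i + 1])
                  and i != gmin]
        if not minima:
            other = 0 if gmin > n // 2 else n - 1
        else:
            def prominence(m: int) -> float:
                lo, hi = (gmin, m) if gmin < m else (m, gmin)
                top = np.nanmax(v[lo : hi + 1])
                return top - max(v[m], v[gmin])

            other = max(minima, key=prominence)
    return _barrier_between(v, gmin, other), gmin


def partition_two_state(
    model: TransitionModel,
    profile: FreeEnergyProfile | None = None,
    method: str = "eigenvector",
    bulk=None,
) -> TwoStatePartition:
    """Split the model into two metastable sets.

    ``eigenvector`` (default) uses the sign structure of the second right
    eigenvector — the standard 2-state metastable decomposition; it falls
    back to ``barrier-split`` when the second eigenvalue is degenerate.
    ``barrier-split`` cuts at the highest free-energy bin between the two
    deepest minima of the profile (between the minimum and the declared
    ``bulk`` bin region when one is given).  The bound set is the one
    containing the free-energy minimum (or the higher-π set when no
    profile is given); the barrier bin is recorded either way.
    """
    n = model.n_states
    if n < 3:
        # two-state toy models: each state is its own set
        if n != 2:
            raise ValueError("need at least 2 states")
        bound = np.array([int(np.argmax(model.pi))])
        unbound = np.setdiff1d(np.arange(2), bound)
        return TwoStatePartition(bound, unbound, "eigenvector-sign", int(unbound[0]))

    values = profile.values if profile is not None else -np.log(model.pi)
    if method == "eigenvector":
        lam = model.eigenvalues
        if lam.size >= 3 and abs(lam[1] - lam[2]) < 1e-10:
            warnings.warn("degenerate second eigenvalue; falling back to barrier-split",
                          stacklevel=2)
            method = "barrier"
        else:
            _, psi2 = second_right_eigenvector(model.T, model.pi)
            a, b = np.flatnonzero(psi2 >= 0), np.flatnonzero(psi2 < 0)
            gmin = int(np.nanargmin(values))
            bound, unbound = (a, b) if gmin in a else (b, a)
            barrier = _barrier_between(values, gmin,
                                       int(unbound[np.argmin(np.abs(unbound - gmin))]))
            z = float(profile.centers[barrier]) if profile is not None else None
            return TwoStatePartition(bound, unbound, "eigenvector-sign", barrier, z)
    barrier, gmin = _barrier_split(values, bulk=bulk)
    idx = np.arange(n)
    if gmin < barrier:
        bound, unbound = idx[:barrier], idx[barrier:]
    else:
        bound, unbound = idx[barrier + 1:], idx[: barrier + 1]
    z = float(profile.centers[barrier]) if profile is not None else None
    return TwoStatePartition(bound, unbound, "barrier-split", barrier, z)


def mfpt(model: TransitionModel, source, target) -> float:
    """Mean first-passage time (ns) from the source set to the target set.

    Solves m_i = 0 on the target and m_i = τ + Σ_j T_ij m_j elsewhere,
    then averages m over the source with the stationary distribution
    restricted (and renormalized) to the source set.
    """
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if target.size == 0:
        raise ValueError("empty target set")
    n = model.n_states
    rest = np.setdiff1d(np.arange(n), target)
    if rest.size == 0:
        return 0.0
    T_rr = model.T[np.ix_(rest, rest)]
    A = np.eye(rest.size) - T_rr
    try:
        m_rest = np.linalg.solve(A, np.full(rest.size, model.lag_ns))
    except np.linalg.LinAlgError as exc:
        raise ValueError("target set unreachable from the source set") from exc
    m = np.zeros(n)
    m[rest] = m_rest
    w = model.pi[source]
    return float(np.sum(w * m[source]) / w.sum())


@dataclass
class KineticsResult:
    """Binding/unbinding times and rate constants at a stated concentration.

    t_in and t_out in ns; k_on in 1/(ns·mM); k_off in 1/ns.  The identity
    k_on·C·t_in = 1 holds exactly by construction.
    """

    t_in: float
    t_out: float
    concentration: float
    transition_state_z: float | None
    partition: TwoStatePartition

    def __post_init__(self):
        if self.t_in <= 0 or self.t_out <= 0:
            raise ValueError("first-passage times must be positive")

    @property
    def k_off(self) -> float:
        return 1.0 / self.t_out

    @property
    def k_on(self) -> float:
        return 1.0 / (self.t_in * self.concentration)

    @property
    def residence_time(self) -> float:
        return self.t_out

    def summary(self) -> dict:
        value, unit = format_time_ns(self.t_out)
        return {
            "t_in_ns": self.t_in,
            "t_out": value,
            "t_out_unit": unit,
            "k_on_per_ns_mM": self.k_on,
            "k_off_per_ns": self.k_off,
            "concentration_mM": self.concentration,
            "transition_state_z": self.transition_state_z,
        }


def rates(
    model: TransitionModel,
    partition: TwoStatePartition,
    concentration: float = DEFAULT_CONCENTRATION_MM,
) -> KineticsResult:
    """t_in, t_out, k_on and the transition-state location for a partition."""
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    t_in = mfpt(model, partition.unbound, partition.bound)
    t_out = mfpt(model, partition.bound, partition.unbound)
    return KineticsResult(
        t_in=t_in, t_out=t_out, concentration=concentration,
        transition_state_z=partition.barrier_z, partition=partition,
    )


# ---------------------------------------------------------------------------
# full unbiased-data pipeline + bootstrap
# ---------------------------------------------------------------------------

def kinetics_from_trajectories(
    trajs,
    grid: BinGrid,
    lag: int,
    kt: float,
    bulk_from: float,
    concentration: float = DEFAULT_CONCENTRATION_MM,
    method: str = "eigenvector",
    mode: str = "sliding",
) -> tuple[KineticsResult, TransitionModel, FreeEnergyProfile]:
    """Counts → reversible MSM → profile → partition → rates, unbiased data."""
    dtrajs = [assign_bins(t, grid) for t in trajs]
    pooled = sum(count_transitions(d, lag, mode) for d in dtrajs)
    states = connected_set(pooled)
    model = estimate_msm_reversible(restrict(pooled, states),
                                    lag_ns=lag * trajs[0].dt, states=states)
    from .estimators.profile import free_energy_from_pi

    ref = np.flatnonzero(np.isin(states, bulk_bins(grid, bulk_from)))
    profile = free_energy_from_pi(model.pi, kt, grid.centers[states], reference_bins=ref)
    part = partition_two_state(model, profile, method=method, bulk=ref)
    return rates(model, part, concentration), model, profile


def bootstrap_kinetics(
    trajs,
    grid: BinGrid,
    lag: int,
    kt: float,
    bulk_from: float,
    concentration: float = DEFAULT_CONCENTRATION_MM,
    n_resamples: int = 100,
    seed: int = 0,
    max_dropped_fraction: float = 0.2,
) -> dict[str, np.ndarray]:
    """Trajectory bootstrap of t_in, t_out and k_on.

    Returns per-replicate arrays; summarize with np.std or percentiles.
    Replicates losing connectivity (or a metastable set) are dropped; more
    than ``max_dropped_fraction`` dropped aborts.
    """
    if len(trajs) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    t_in, t_out, k_on = [], [], []
    dropped = 0
    for b in range(n_resamples):
        rng = np.random.default_rng(child_seed(seed, b))
        sample = [trajs[i] for i in rng.integers(0, len(trajs), size=len(trajs))]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res, _, _ = kinetics_from_trajectories(
                    sample, grid, lag, kt, bulk_from, concentration
                )
        except (ValueError, np.linalg.LinAlgError):
            dropped += 1
            continue
        t_in.append(res.t_in)
        t_out.append(res.t_out)
        k_on.append(res.k_on)
    if dropped > max_dropped_fraction * n_resamples:
        raise RuntimeError(f"{dropped}/{n_resamples} bootstrap replicates dropped")
    return {"t_in": np.array(t_in), "t_out": np.array(t_out), "k_on": np.array(k_on),
            "n_dropped": dropped}


# ---------------------------------------------------------------------------
# published reference kinetics (input data for consistency checks)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceKinetics:
    """One published row: system, ligand, t_in (ns), t_out, k_on (1/(ns·mM))."""

    system: str
    ligand: str
    t_in_ns: float
    t_in_err_ns: float
    t_out_value: float
    t_out_unit: str
    k_on: float
    k_on_err: float

    @property
    def t_out_ns(self) -> float:
        from .units import time_to_ns

        return time_to_ns(self.t_out_value, self.t_out_unit)


#: Reported binding kinetics of (−)- and (+)-morphine with the μ-opioid
#: receptor under the four protonation-state combinations of the
#: binding-site aspartates D114(2.50) and D147(3.32), at 0.70 mM ligand.
REFERENCE_TABLE = (
    ReferenceKinetics("D2.50-charged/D3.32-charged", "(-)-morphine", 99.07, 5.37, 0.30, "s", 0.01434, 0.00067),
    ReferenceKinetics("D2.50-charged/D3.32-charged", "(+)-morphine", 63.79, 2.12, 37.36, "us", 0.02227, 0.00109),
    ReferenceKinetics("D2.50-charged/D3.32-neutral", "(-)-morphine", 336.32, 16.26, 4.36, "us", 0.00422, 0.00022),
    ReferenceKinetics("D2.50-charged/D3.32-neutral", "(+)-morphine", 326.46, 46.44, 49.87, "us", 0.00435, 0.00030),
    ReferenceKinetics("D2.50-neutral/D3.32-charged", "(-)-morphine", 523.36, 38.43, 1.90, "us", 0.00271, 0.00013),
    ReferenceKinetics("D2.50-neutral/D3.32-charged", "(+)-morphine", 46.82, 1.21, 4.57, "ms", 0.03035, 0.00076),
    ReferenceKinetics("D2.50-neutral/D3.32-neutral", "(-)-morphine", 1153.46, 68.69, 52.72, "us", 0.001231, 0.00010),
    ReferenceKinetics("D2.50-neutral/D3.32-neutral", "(+)-morphine", 198.76, 13.02, 59.40, "us", 0.00715, 0.00058),
)

REFERENCE_CONCENTRATION_MM = 0.70


def kon_consistency(rows=REFERENCE_TABLE, concentration: float = REFERENCE_CONCENTRATION_MM):
    """Relative errors of k_on = 1/(t_in·C) against the published k_on values."""
    computed = np.array([1.0 / (r.t_in_ns * concentration) for r in rows])
    published = np.array([r.k_on for r in rows])
    return computed, published, np.abs(computed - published) / published


def residence_time_ratio(slow: ReferenceKinetics, fast: ReferenceKinetics) -> float:
    """Ratio of two residence times (dimensionless)."""
    return slow.t_out_ns / fast.t_out_ns
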