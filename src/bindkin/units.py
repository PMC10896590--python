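"""Unit conventions and conversions.

Everything in the codebase is expressed in a single fixed unit ladder:
lengths in Å, times in ns, energies in kcal/mol (or thermal units kT
where a function says so), concentrations in mM, rate constants in
1/(ns·mM).  This module is the only place where conversions live.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_PER_MOL_K = 1.987204259e-3

#: Default thermal energy in kcal/mol (physiological temperature, ~310 K).
DEFAULT_KT = 0.6163

#: Default ligand concentration in mM (one ligand per simulation box in the
#: study this emulates).
DEFAULT_CONCENTRATION_MM = 0.70


def kt_from_temperature(temperature_k: float) -> float:
    """Thermal energy kT in kcal/mol at ``temperature_k`` kelvin."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KCAL_PER_MOL_K * temperature_k


# presentation ladder for times: internal unit is always ns
_TIME_LADDER = (("ns", 1.0), ("us", 1e3), ("ms", 1e6), ("s", 1e9))


def format_time_ns(t_ns: float) -> tuple[float, str]:
    """Scale a time in ns to the largest unit keeping |value| >= 0.1
    (so 3e8 ns reads as 0.30 s rather than 300 ms).

    Returns ``(value, unit)`` with unit in {ns, us, ms, s}.  Used only at
    presentation time; internal arithmetic never leaves ns.
    """
    value, unit = t_ns, "ns"
    for u, factor in _TIME_LADDER:
        if abs(t_ns) >= 0.1 * factor:
            value, unit = t_ns / factor, u
    return value, unit


def time_to_ns(value: float, unit: str) -> float:
    """Convert a (value, unit) pair back to ns; unit in {ns, us, ms, s}."""
    for u, factor in _TIME_LADDER:
        if unit == u:
            return value * factor
    raise ValueError(f"unknown time unit {unit!r}")
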