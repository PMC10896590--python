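"""Free-energy profiles along the reaction coordinate.

A profile holds per-bin free energies in kcal/mol referenced so that the
mean over a declared set of bulk (unbound) bins is zero — binding wells
then read directly as negative well depths relative to the unbound
plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

REFERENCE_BULK = "bulk-mean-zero"
REFERENCE_MAX = "max-zero"


@dataclass
class FreeEnergyProfile:
    """Per-bin free energies F(z) with optional bootstrap errors.

    ``centers`` are bin centers in Å; ``values`` and ``errors`` in
    kcal/mol.  ``reference`` records the zero convention.
    """

    centers: np.ndarray
    values: np.ndarray
    kt: float
    errors: np.ndarray | None = None
    reference: str = REFERENCE_BULK

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.centers.shape != self.values.shape:
            raise ValueError("centers and values must have the same shape")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.values.shape:
                raise ValueError("errors must match values in shape")

    @property
    def well_depth(self) -> float:
        """Minimum of F in kcal/mol (negative for a bound well)."""
        return float(np.nanmin(self.values))

    @property
    def well_position(self) -> float:
        """Bin center (Å) of the free-energy minimum."""
        return float(self.centers[np.nanargmin(self.values)])

    def in_kt(self) -> np.ndarray:
        return self.values / self.kt


def reference_shift(values: np.ndarray, reference_bins) -> tuple[np.ndarray, str]:
    """Shift so the mean over ``reference_bins`` is zero (bulk convention).

    An empty reference set falls back to max-F = 0 with a warning tag.
    """
    values = np.asarray(values, dtype=float)
    reference_bins = np.asarray(reference_bins, dtype=int) if reference_bins is not None else np.array([], int)
    if reference_bins.size == 0:
        warnings.warn("empty reference bin set; falling back to max-F = 0", stacklevel=3)
        return values - np.nanmax(values), REFERENCE_MAX
    return values - float(np.nanmean(values[reference_bins])), REFERENCE_BULK


def free_energy_from_pi(
    pi: np.ndarray,
    kt: float,
    centers: np.ndarray,
    reference_bins=None,
    errors: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """F_i = −kT·ln π_i + c, with c fixing the bulk reference to zero.

    ``reference_bins`` index into the profile (i.e. into ``pi``); they
    should cover the flat unbound plateau.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("stationary probabilities must be positive on reported bins")
    values, tag = reference_shift(-kt * np.log(pi), reference_bins)
    return FreeEnergyProfile(centers=np.asarray(centers, float), values=values,
                             kt=kt, errors=errors, reference=tag)
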