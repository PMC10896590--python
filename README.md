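# bindkin

Thermodynamics and kinetics of ligand binding from reaction-coordinate
trajectories, plus the structural statistics that usually accompany such
an analysis.

`bindkin` is aimed at molecular-simulation practitioners who study how a
small molecule binds and leaves a receptor — the motivating system is the
stereoselective recognition of morphine enantiomers by the μ-opioid
receptor, where the decisive observables are the binding free-energy
profile F(z) along a separation coordinate z and the drug residence time
t_out = 1/k_off. The package implements the full analysis chain on 1D
reaction-coordinate data:

- **Markov state models (MSM)**: z is discretized into bins (default
  0.5 Å), transition counts C_ij(τ) are collected at lag τ, and the
  maximum-likelihood *reversible* transition matrix is estimated
  (detailed balance π_i T_ij = π_j T_ji enforced exactly). The lag is
  validated by implied-timescale convergence, t_i(τ) = −τ/ln λ_i(τ).
- **dTRAM**: from mixed ensembles — umbrella windows with harmonic bias
  b^k(z) = ½k_umb(z−z0)² plus unbiased runs — the unbiased stationary
  distribution π is estimated by maximizing the joint likelihood
  ∑_k ∑_ij C^k_ij ln p^k_ij over per-ensemble transition matrices in
  detailed balance with π_i e^{−b^k_i}. The free-energy profile is
  F_i = −kT ln π_i, referenced so the unbound bulk plateau averages to
  zero, with trajectory-bootstrap error bars.
- **Kinetics**: the MSM is coarse-grained into bound/unbound metastable
  states (second-eigenvector sign split, or a barrier split at the
  highest bin between well and bulk). Then t_in = MFPT(unbound→bound),
  t_out = MFPT(bound→unbound), k_off = 1/t_out and
  k_on = 1/(t_in·C) at ligand concentration C (default 0.70 mM).
- **Structure layer**: Kabsch superposition, RMSD/RMSF, dynamic
  cross-correlation maps of Cα displacements, correlation-weighted
  communication networks (edge weight −log|c_ij| over a contact map)
  with shortest paths, dihedral and pair-distance monitors.
- **Interaction fingerprints**: per-snapshot detectors for salt bridges,
  hydrogen bonds, hydrophobic contacts and single-water bridges,
  aggregated to per-residue occupancy probabilities.
- **Synthetic data with analytic oracles**: overdamped Langevin dynamics
  on analytic 1D potentials (binding funnels, double wells), exact bin
  free energies by quadrature, the closed-form 1D mean first-passage time
  T(a→b) = D⁻¹∫_a^b e^{βU(y)}∫_refl^y e^{−βU(x)} dx dy, correlated
  Gaussian coordinate frames, and toy receptor–ligand complexes with
  known interaction geometry. Every estimator is tested against these
  ground truths.

## Worked example

Estimate binding kinetics on the shipped `shallow_funnel` preset (a bound
well at z = 10 Å behind a 4 kT barrier at z = 16 Å), from twelve unbiased
binding/unbinding trajectories:

```python
import numpy as np
from bindkin.discretize import BinGrid, assign_bins
from bindkin.estimators import implied_timescales, select_lag
from bindkin.kinetics import kinetics_from_trajectories
from bindkin.synthdata import LangevinParams, child_seed, preset, simulate_langevin
from bindkin.units import format_time_ns

pot = preset("shallow_funnel")
trajs = [
    simulate_langevin(pot, LangevinParams(
        diffusion=10.0, dt=0.005, n_steps=200_000,
        seed=child_seed(7, i), initial_z=10.0))
    for i in range(12)
]
grid = BinGrid.from_width(5.0, 25.0, 0.5)
lag = select_lag(implied_timescales([assign_bins(t, grid) for t in trajs],
                                    lags=[2, 5, 10, 20]))
result, model, profile = kinetics_from_trajectories(
    trajs, grid, lag=lag, kt=0.6163, bulk_from=18.0, method="barrier")
value, unit = format_time_ns(result.t_out)
print(f"validated lag      : {lag} steps ({lag * trajs[0].dt:.3f} ns)")
print(f"well depth         : {profile.well_depth:+.2f} kcal/mol at z = {profile.well_position:.2f} A")
print(f"transition state   : z = {result.transition_state_z:.2f} A")
print(f"binding time t_in  : {result.t_in:.1f} ns")
print(f"residence t_out    : {value:.1f} {unit}")
print(f"k_on (0.70 mM)     : {result.k_on:.5f} 1/(ns mM)")
```

prints

```
validated lag      : 5 steps (0.025 ns)
well depth         : -1.42 kcal/mol at z = 10.25 A
transition state   : z = 16.25 A
binding time t_in  : 6.8 ns
residence t_out    : 26.4 ns
k_on (0.70 mM)     : 0.21128 1/(ns mM)
```

The well depth is the minimum of F(z) relative to the unbound plateau
(here ≈ 2.3 kT, the 2.5 kT well minus bin-averaging); the residence time
can be checked against the closed-form MFPT for this potential,
`analytic_mfpt(pot, 10.0, 16.0, 10.0)` ≈ 24.1 ns. The identity
k_on·C·t_in = 1 holds exactly by construction.

A command-line interface mirrors the library:

```bash
bindkin synth umbrella --preset double_well_8kT --out windows/
bindkin dtram windows/*.tsv --bulk-from 18 --out profile.tsv
bindkin kinetics report traj1.tsv traj2.tsv --bulk-from 18 --out table.tsv
bindkin struct dccm frames.pdb --out dccm.tsv
bindkin fp run complex.pdb --out fingerprints.tsv
```

## Layout

```
src/bindkin/synthdata/   potentials, Langevin sampler, oracles, toy structures
src/bindkin/discretize.py  bin grids, transition counting, connected sets
src/bindkin/estimators/  reversible MSM, dTRAM, implied timescales, bootstrap
src/bindkin/kinetics.py  two-state partition, MFPT, rates, published table
src/bindkin/structure.py superposition, RMSD/RMSF, DCCM, networks, monitors
src/bindkin/fingerprints.py  interaction detectors and occupancy tables
src/bindkin/io.py        PDB/XYZ/TSV/JSON/YAML readers and writers
src/bindkin/cli.py       the `bindkin` command
docs/methods.md          model assumptions, defaults, numerical choices
```
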