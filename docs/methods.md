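# Methods

This note records the models behind `bindkin`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests
do and do not demonstrate about real simulation data.

## The physical picture

The package analyses ligand binding and unbinding projected onto a single
reaction coordinate z (Å) — in the motivating application, the separation
of a morphine enantiomer from the μ-opioid receptor binding pocket along
the pore axis. The coordinate is treated as given input; `bindkin` makes
no attempt to define it geometrically. A binding event appears as a deep
free-energy well (the bound pose) separated from a flat bulk region (the
unbound ligand) by a barrier whose location is reported as the transition
state. Two observables summarize the process: the well depth of F(z)
relative to the bulk plateau (thermodynamics) and the residence time
t_out = 1/k_off together with k_on (kinetics).

## Units and constants

Å, ns, kcal/mol, mM, and 1/(ns·mM) everywhere; 1-based residue numbers.
The default thermal energy is kT = 0.6163 kcal/mol, physiological
temperature (~310 K). All conversions live in `bindkin.units`; times are
auto-scaled to ns/μs/ms/s only at presentation (largest unit keeping the
value ≥ 0.1, so 3×10⁸ ns prints as 0.30 s).

## Discretization

Reaction-coordinate values are binned on a uniform grid, default width
0.5 Å — the resolution at which well and transition-state positions are
meaningfully reported on this kind of profile. Bins are half-open
[e_i, e_{i+1}) with the last bin closed. Out-of-grid frames become
sentinels and are *dropped, not clamped*: clamping would silently inflate
the edge-bin populations and distort edge free energies. Transition
counting at lag τ uses sliding windows by default (every start time t;
better statistics) with a strided mode (t = 0, τ, 2τ, …) available for
strict independence checks. Counts never cross trajectory boundaries, and
pairs touching a sentinel are skipped. All estimation is restricted to
the largest connected component of the symmetrized count graph
(C + Cᵀ > 0), matching the reversible estimators.

## Reversible MSM

`estimate_msm_reversible` maximizes ∏ T_ij^{C_ij} subject to detailed
balance via the standard self-consistent iteration on symmetric fluxes
x_ij = π_i T_ij, converged when π changes by < 1e-10 (max norm).
Eigenvalues come from the π-symmetrized similar matrix
D_π^{1/2} T D_π^{-1/2} (symmetric, so real by construction). Every
emitted model *asserts* row-stochasticity, stationarity and detailed
balance rather than assuming them.

Lag validation: implied timescales t_i(τ) = −τ/ln λ_i(τ) are scanned over
a lag list; the smallest lag whose slowest timescale changes by < 5%
relative to the next tested lag is selected. The 5% threshold is this
package's choice of convergence criterion — a standard operating
definition of "the curve has flattened".

## dTRAM

The unbiased stationary distribution π is estimated jointly from all
ensembles (umbrella windows with known bias energies b^k_i in kT, plus
unbiased runs) by maximizing

L = ∑_k ∑_ij C^k_ij ln p^k_ij

over per-ensemble transition matrices p^k that are row-stochastic and in
detailed balance with q^k_i ∝ π_i e^{−b^k_i}. Ensembles are
*thermodynamic states*: trajectories sharing one bias vector pool their
counts, so the all-unbiased case reduces exactly to the pooled reversible
MSM (this is asserted to 1e-6 in the tests). Constant shifts of a bias
row are a gauge and provably cannot move π; each row is shifted by its
minimum before exponentiation to avoid overflow.

Solver: for *fixed* π, the optimal p^k is the classic
reversible-MLE-with-prescribed-stationary-vector fixed point in the
Lagrange multipliers ν^k_i; the outer problem is solved by L-BFGS ascent
of the profile likelihood over ln π, whose gradient is available in
closed form by the envelope theorem, ∂L/∂ln π_i = ∑_k (ν^k_i − c^k_i).
A naive alternating fixed-point update of π was tried first and is
unstable (a positive feedback between π and ν collapses tail bins); the
direct optimization is robust and converges in a few hundred likelihood
evaluations. The inner solver operates on the flattened nonzero entries
of the symmetrized count tensor — transitions along a 1D coordinate are
banded, so this is ~50× sparser than dense sweeps. Convergence is
declared when the profile-likelihood gradient per observed transition
falls below 1e-7.

Free energies are F_i = −kT ln π_i + c with c fixing the *mean over
user-declared bulk bins* to zero, so well depths read directly as
negative values against the unbound plateau; with no usable reference the
profile falls back to max-F = 0 and tags itself accordingly. Profile
errors are per-bin standard deviations over bootstrap replicates; the
resampling unit is the *whole trajectory* (respecting within-trajectory
temporal correlation), default B = 100. Replicates that lose connectivity
or the reference region are dropped and counted; more than 20% dropped
aborts the error estimate.

## Kinetics

The validated MSM is reduced to two metastable sets. Default: sign split
of the second right eigenvector (the 2-state metastable decomposition),
falling back to a barrier split when λ₂ is numerically degenerate. The
barrier split cuts at the highest free-energy bin between the global
minimum and the declared bulk region; without a bulk declaration the
partner minimum is chosen by barrier *prominence*, because a plain
"second-deepest minimum" rule is fooled by noise wiggles on a flat
plateau. On 1D diffusive funnels the eigenvector split tends to land a
few bins inside the uphill flank rather than at the barrier top, so the
barrier split is the more faithful choice when the transition-state
location matters; both are exposed.

MFPTs solve m_i = 0 on the target and m_i = τ + Σ_j T_ij m_j elsewhere;
the reported time averages m over the source set weighted by the
stationary distribution restricted to it (the standard MSM convention).
Then t_in = MFPT(unbound→bound), t_out = MFPT(bound→unbound),
k_off = 1/t_out, k_on = 1/(t_in·C). The concentration C is a user input
(default 0.70 mM, one ligand in a simulation-box volume); k_on·C·t_in = 1
holds identically. The transition state is reported as the barrier-bin
center, matching how such locations are quoted (a single z value);
internal times never leave ns.

The package also ships, as *input data*, the published kinetic table for
(−)/(+)-morphine binding the μ-opioid receptor under four protonation
states of the binding-site aspartates D114(2.50)/D147(3.32)
(`bindkin.kinetics.REFERENCE_TABLE`). Tests and the reproduction script
check its internal arithmetic: all eight printed k_on values equal
1/(t_in·0.70 mM) within 1% (the ~0.5–0.7% residual is consistent with the
source rounding unprinted internal values), and the two printed
residence-time contrasts evaluate to 8.0×10³ and 2.4×10³ at two
significant figures.

## Structure layer

Superposition is least-squares rigid-body (Kabsch; proper rotations only)
with the optimal rotation obtained from `scipy`'s `align_vectors` and the
RMSD recomputed from the transformed coordinates (the solver's own
residual norm carries ~1e-7 float noise). RMSF and DCCM use iterative
mean-structure superposition (two passes by default; single-pass by
flag). DCCM is c_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) with Δr deviations
from each atom's trajectory mean; zero-variance atoms yield NaN rows (and
are excluded from network construction rather than zero-filled); values
may exceed 1 only by < 1e-12 (clipped), anything larger is an error.

Communication networks connect residues in persistent contact (default
Cα–Cα ≤ 8 Å in ≥ 75% of frames — customary defaults, configurable) with
edge weight −log|c_ij| (|c| clipped to (1e-12, 1−1e-12)); shortest paths
are Dijkstra over these nonnegative weights. Dihedrals follow the IUPAC
sign convention (cis = 0°, trans = 180°, value in (−180°, 180°]);
collinear mid-bond geometry returns NaN per frame.

## Interaction fingerprints

Detector criteria (all configurable, recorded in output metadata):
salt bridge — opposite formal charges with any charged-group N–O pair
≤ 4.0 Å; hydrogen bond — donor–acceptor heavy atoms ≤ 3.5 Å and
D–H···A ≥ 135° when the donor hydrogen is present (distance-only and
flagged when it is not); hydrophobic — apolar–apolar heavy atoms ≤ 4.5 Å;
water bridge — one water oxygen within H-bond distance of both a ligand
polar atom and a residue polar atom (single-water bridges only). These
cutoffs are customary literature defaults. A residue–type pair counts at
most once per snapshot, so the aggregate is an occupancy probability.
Ligand chemistry is declared by a small template (atom name → charge,
polarity, donor hydrogens) rather than perceived from connectivity;
histidine charge is user-declared per residue. Protein typing uses
standard atom-name tables, with carboxylate/amide/guanidinium carbons
excluded from the apolar set.

## Synthetic data and what the tests show

The generator produces overdamped Langevin (Euler–Maruyama) trajectories
on analytic potentials expressed in kT: z_{t+1} = z_t − D ∂(βU_eff) dt +
√(2D dt) ξ. A stability check warns when dt·D·max|βU′|² reaches the
domain span; reflecting boundaries fold excursions back, absorbing ends
truncate. Umbrella windows derive child seeds deterministically from the
parent seed, so every dataset is a pure function of (parameters, seed).

Shipped presets fix the study conditions used throughout the tests:

- `double_well_8kT` — Gaussian wells of 8 kT and 4 kT depth at z = 5 and
  15 Å on [0, 20] Å; sampled by 10 umbrella windows (centers 1–19 Å,
  k_umb = 1 kcal/mol/Å², 2×10⁵ steps of 1 ps each) plus one unbiased run.
  dTRAM recovers the analytic bin free energies within 0.3 kT RMSE on
  bins with ≥ 100 samples (~0.1–0.2 kT in practice).
- `shallow_funnel` — 2.5 kT well at z = 10 Å plus a 1.5 kT barrier bump
  at 16 Å (4 kT total escape barrier), D = 10 Å²/ns. Twelve unbiased
  1 μs trajectories give an MSM whose residence time matches the
  closed-form MFPT (well bottom → barrier) within 25%; the residual
  ~10–20% gap combines the π-weighted source average (which includes
  pre-well plateau bins), finite-timestep crossing detection in the data,
  and bin discretization.
- `morphinelike` — an 8 kT bound well at z = 10 Å with a small barrier
  near 22.5 Å before a flat bulk tail, as an homage to the deep
  agonist-binding profile that motivates the package; its well depth
  reads ≈ −4.9 kcal/mol at the default kT.

Potential shapes, window spacing, force constants, per-window lengths and
D were chosen once for testability — they make barrier recrossings
frequent enough to estimate on a desktop — not to reproduce any
particular molecular system's magnitudes. The 1D surrogate deliberately
omits almost everything that makes real MD hard: orthogonal slow degrees
of freedom (protein conformational gating, protonation dynamics),
position-dependent diffusion, anisotropic solvent effects, and
force-field error. Passing tests therefore demonstrate that the
*estimators* are correct on data satisfying their own assumptions; they
say nothing about whether a given molecular system's reaction coordinate
is Markovian at any lag.

Analytic oracles: bin free energies are −kT ln ∫_bin e^{−βU} dz by
per-bin Simpson quadrature (65 points/bin); the MFPT double integral uses
a cumulative-Simpson inner integral on a dense grid built from two
segments meeting exactly at the start point, with a reflecting wall on
the far side of the start. Correlated Gaussian frames apply one PSD
covariance independently per Cartesian axis, so the displacement
correlation equals the normalized covariance; these frames share a lab
frame by construction, and the DCCM generator tests run without
superposition — fitting would remove six rigid degrees of freedom and
bias the comparison. Toy complexes place a morphine-like ligand (charged
amine, phenol hydroxyl, apolar carbons) against an Asp/Ser/Leu/water
environment at analytically chosen distances and angles, one preset per
detector plus moved-apart negatives, so the fingerprint truth table is
known by construction.

## Numerical choices and degenerate inputs

- MSM tolerance 1e-10 (max π change); dTRAM gradient tolerance 1e-7 per
  observed transition, up to three L-BFGS restarts.
- Empty umbrella-center lists, empty trajectories, non-increasing bin
  edges, non-PSD covariances, non-finite biases, zero concentrations and
  unknown presets are rejected with specific messages; ensembles with
  zero counts are excluded with a warning; lags exceeding the trajectory
  length yield empty counts with a warning.
- Bootstrap with B = 1 reports zero error on covered bins (a width-zero
  interval, not an estimate).
- Two-state toy models (n = 2) are partitioned trivially; degenerate λ₂
  triggers the barrier-split fallback with a warning.

## Known limitations

- dTRAM here supports harmonic (or zero) biases on one coordinate; no
  TRAM/xTRAM/MBAR generalizations, no multi-temperature ensembles.
- No transition-path theory fluxes or >2-state rate models; the two-state
  reduction is the intended end point.
- The structure layer reads multi-model PDB and XYZ only (text formats);
  binary trajectory formats are out of scope by design.
- Fingerprint chemistry is declared, not perceived; exotic interaction
  types (π-stacking, cation–π, halogen bonds) are not detected.
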