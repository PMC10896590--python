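"""Brownian-dynamics sampler: stationary laws, bias behaviour, determinism."""

import numpy as np
import pytest
from scipy import stats

from bindkin.discretize import BinGrid
from bindkin.synthdata import (
    BiasSpec,
    LangevinParams,
    UNBIASED,
    first_passage_times,
    make_umbrella_set,
    simulate_langevin,
)
from bindkin.synthdata.potentials import Potential, preset


def params(**over):
    base = dict(diffusion=10.0, dt=0.002, n_steps=100_000, seed=1, initial_z=10.0)
    base.update(over)
    return LangevinParams(**base)


class TestStationaryLaw:
    def test_flat_potential_uniform_occupancy(self):
        pot = preset("flat20")
        traj = simulate_langevin(pot, params(n_steps=400_000))
        grid = BinGrid.from_width(0.0, 20.0, 2.0)
        freq = np.bincount(grid.assign(traj.z), minlength=grid.n_bins) / traj.z.size
        # standard error of a bin frequency from the effective sample size;
        # the slowest diffusive mode on [0, L] relaxes on L^2 / (pi^2 D)
        tau_steps = 20.0**2 / (np.pi**2 * 10.0) / 0.002
        n_eff = traj.z.size / tau_steps
        p = 1.0 / grid.n_bins
        se = np.sqrt(p * (1 - p) / n_eff)
        assert np.all(np.abs(freq - p) < 3 * se)

    def test_harmonic_variance_matches_kt_over_k(self):
        pot = Potential("harmonic", {"k": 1.0, "center": 5.0}, domain=(0, 10))
        traj = simulate_langevin(pot, params(n_steps=400_000, initial_z=5.0))
        assert traj.z.var() == pytest.approx(1.0, rel=0.05)

    def test_boltzmann_histogram_chi2(self):
        """Long-run histogram matches exp(-U) by a chi-square test at alpha=0.01."""
        pot = Potential("harmonic", {"k": 1.0, "center": 10.0}, domain=(5, 15))
        traj = simulate_langevin(pot, params(n_steps=400_000))
        grid = BinGrid.from_width(6.0, 14.0, 0.5)
        # fine sub-bin quadrature of the expected Boltzmann weights
        p = np.empty(grid.n_bins)
        for i in range(grid.n_bins):
            zz = np.linspace(grid.edges[i], grid.edges[i + 1], 21)
            p[i] = np.trapezoid(np.exp(-pot.energy(zz)), zz)
        p /= p.sum()
        # thin past the harmonic relaxation time kT/(k D) before testing
        stride = 2 * max(1, int(1.0 / 10.0 / 0.002))
        zthin = traj.z[::stride]
        zthin = zthin[(zthin >= 6.0) & (zthin <= 14.0)]
        thin = np.bincount(grid.assign(zthin), minlength=grid.n_bins)
        keep = p * thin.sum() >= 5
        chi2 = np.sum((thin[keep] - p[keep] * thin.sum()) ** 2 / (p[keep] * thin.sum()))
        crit = stats.chi2.ppf(0.99, keep.sum() - 1)
        assert chi2 < crit


class TestMechanics:
    def test_same_seed_bit_identical(self):
        pot = preset("flat20")
        a = simulate_langevin(pot, params(n_steps=5_000))
        b = simulate_langevin(pot, params(n_steps=5_000))
        assert np.array_equal(a.z, b.z)

    def test_different_seed_differs(self):
        pot = preset("flat20")
        a = simulate_langevin(pot, params(n_steps=5_000))
        b = simulate_langevin(pot, params(n_steps=5_000, seed=2))
        assert not np.array_equal(a.z, b.z)

    def test_reflecting_keeps_domain(self):
        pot = preset("flat20")
        traj = simulate_langevin(pot, params(n_steps=50_000, dt=0.01))
        assert traj.z.min() >= 0.0 and traj.z.max() <= 20.0

    def test_absorbing_end_truncates(self):
        pot = Potential("flat", {}, domain=(0.0, 20.0),
                        boundary=("reflecting", "absorbing"))
        traj = simulate_langevin(pot, params(n_steps=200_000, dt=0.01, initial_z=19.0))
        assert len(traj) < 200_001
        assert traj.z[-1] == pytest.approx(20.0)

    def test_stability_warning_for_stiff_step(self):
        pot = Potential("harmonic", {"k": 500.0, "center": 5.0}, domain=(0, 10))
        with pytest.warns(RuntimeWarning, match="unstable"):
            simulate_langevin(pot, params(n_steps=10, dt=0.05, initial_z=5.0))

    def test_initial_z_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="outside domain"):
            simulate_langevin(preset("flat20"), params(initial_z=-3.0))


class TestUmbrellaSet:
    def test_empty_centers_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_umbrella_set(preset("flat20"), [], 1.0, params())

    def test_means_near_centers_on_flat_potential(self):
        pot = preset("flat20")
        centers = [4.0, 8.0, 12.0, 16.0, 18.0]
        trajs = make_umbrella_set(pot, centers, 2.0, params(n_steps=50_000))
        sigma2 = 0.6163 / 2.0  # kT / k_umb
        for c, t in zip(centers, trajs):
            tau = sigma2 / 10.0 / 0.002  # relaxation time in steps
            se = np.sqrt(sigma2 / (len(t) / tau))
            assert abs(t.z.mean() - c) < 3 * max(se, 0.02)

    def test_windows_cover_barrier_unbiased_cannot(self):
        pot = preset("double_well_8kT")
        par = params(dt=0.001, n_steps=20_000, initial_z=5.0)
        windows = make_umbrella_set(pot, np.arange(1.0, 19.5, 2.0), 1.0, par)
        unbiased = simulate_langevin(pot, par)
        grid = BinGrid.from_width(0.0, 20.0, 0.5)
        pooled = set()
        for w in windows:
            pooled.update(np.unique(grid.assign(w.z)).tolist())
        solo = set(np.unique(grid.assign(unbiased.z)).tolist())
        assert solo < pooled  # strict superset: windows reach bins the
        #                       unbiased run of equal length never visits

    def test_zero_force_constant_statistically_unbiased(self):
        pot = preset("flat20")
        par = params(n_steps=400_000)
        biased = make_umbrella_set(pot, [10.0], 0.0, par)[0]
        unbiased = simulate_langevin(
            pot, LangevinParams(diffusion=10.0, dt=0.002, n_steps=400_000,
                                seed=biased.seed, initial_z=10.0))
        # identical seed and zero bias: the dynamics coincide exactly
        assert np.array_equal(biased.z, unbiased.z)
        # and against an independent unbiased run the laws agree (two-sample
        # KS at alpha=0.01, thinned past the global diffusive relaxation)
        other = simulate_langevin(pot, params(n_steps=400_000, seed=99))
        stride = int(20.0**2 / (np.pi**2 * 10.0) / 0.002)
        ks = stats.ks_2samp(biased.z[::stride], other.z[::stride])
        assert ks.pvalue > 0.01

    def test_deterministic_child_seeds(self):
        pot = preset("flat20")
        a = make_umbrella_set(pot, [5.0, 10.0], 1.0, params(n_steps=1_000))
        b = make_umbrella_set(pot, [5.0, 10.0], 1.0, params(n_steps=1_000))
        for x, y in zip(a, b):
            assert np.array_equal(x.z, y.z)
            assert x.seed == y.seed


class TestFirstPassage:
    def test_replicas_all_absorbed_and_positive(self):
        pot = preset("flat20")
        t = first_passage_times(pot, params(dt=0.01, n_steps=500_000),
                                start=10.0, target=15.0, n_replicas=50)
        assert t.shape == (50,) and np.all(t > 0)

    def test_unabsorbed_replicas_raise(self):
        pot = preset("flat20")
        with pytest.raises(RuntimeError, match="not absorbed"):
            first_passage_times(pot, params(dt=0.001, n_steps=10),
                                start=0.5, target=19.5, n_replicas=5)
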