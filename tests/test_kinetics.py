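"""Two-state coarse-graining, MFPTs, rate constants, published-table checks."""

import numpy as np
import pytest

from bindkin.estimators.msm import TransitionModel, estimate_msm_reversible
from bindkin.estimators.profile import FreeEnergyProfile
from bindkin.kinetics import (
    REFERENCE_TABLE,
    KineticsResult,
    bootstrap_kinetics,
    kinetics_from_trajectories,
    kon_consistency,
    mfpt,
    partition_two_state,
    rates,
    residence_time_ratio,
)
from bindkin.synthdata import analytic_mfpt
from bindkin.units import format_time_ns


def two_state_model(T=None, lag=1.0):
    T = np.array([[0.9, 0.1], [0.3, 0.7]]) if T is None else np.asarray(T)
    evals, evecs = np.linalg.eig(T.T)
    pi = np.real(evecs[:, np.argmax(evals.real)])
    pi /= pi.sum()
    return TransitionModel(T=T, pi=pi, lag_ns=lag)


class TestPartition:
    def test_two_state_toy_split(self):
        part = partition_two_state(two_state_model())
        assert part.bound.tolist() == [0]
        assert part.unbound.tolist() == [1]

    def test_symmetric_double_well_mirror_split(self):
        """A symmetric birth-death chain over an even number of bins splits
        into mirror-image halves at the central barrier."""
        n = 10
        F = np.abs(np.arange(n) - (n - 1) / 2)  # V-shaped barrier at center
        F = F.max() - F  # invert: wells at the ends, barrier mid
        pi = np.exp(-F)
        pi /= pi.sum()
        # reversible rates from detailed balance on a chain
        T = np.zeros((n, n))
        for i in range(n - 1):
            T[i, i + 1] = 0.2 * min(1.0, pi[i + 1] / pi[i])
            T[i + 1, i] = 0.2 * min(1.0, pi[i] / pi[i + 1])
        np.fill_diagonal(T, 1.0 - T.sum(axis=1))
        model = TransitionModel(T=T, pi=pi, lag_ns=1.0)
        prof = FreeEnergyProfile(centers=np.arange(n, dtype=float), values=F,
                                 kt=1.0)
        part = partition_two_state(model, prof)
        assert part.bound.size == part.unbound.size == n // 2
        assert set(part.bound.tolist()) | set(part.unbound.tolist()) == set(range(n))

    def test_eigenvector_and_barrier_methods_agree_on_funnel(
        self, funnel_unbiased_data, kt
    ):
        _, trajs, grid = funnel_unbiased_data
        res_e, model, prof = kinetics_from_trajectories(
            trajs, grid, lag=5, kt=kt, bulk_from=18.0, method="eigenvector")
        res_b, _, _ = kinetics_from_trajectories(
            trajs, grid, lag=5, kt=kt, bulk_from=18.0, method="barrier")
        n = model.n_states
        agree = (np.isin(np.arange(n), res_e.partition.bound)
                 == np.isin(np.arange(n), res_b.partition.bound)).mean()
        assert agree >= 0.9  # the methods may disagree on a few plateau bins


class TestMFPT:
    def test_closed_form_two_state(self):
        model = two_state_model(T=[[0.9, 0.1], [0.2, 0.8]])
        assert mfpt(model, [0], [1]) == pytest.approx(10.0, rel=1e-12)

    def test_matches_absorbing_chain_simulation(self):
        """Linear-system MFPT equals brute-force chain simulation within 3 SE."""
        X = np.array([[8.0, 2.0, 1.0],
                      [2.0, 6.0, 3.0],
                      [1.0, 3.0, 7.0]])  # symmetric fluxes => reversible T
        T = X / X.sum(axis=1, keepdims=True)
        model = two_state_model(T=T)
        expected = mfpt(model, [0], [2])
        rng = np.random.default_rng(12)
        cum = np.cumsum(T, axis=1)
        times = np.empty(4000)
        for r in range(times.size):
            s, t = 0, 0
            while s != 2:
                s = int(np.searchsorted(cum[s], rng.random()))
                t += 1
            times[r] = t
        se = times.std(ddof=1) / np.sqrt(times.size)
        assert abs(times.mean() - expected) < 3 * se

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="empty target"):
            mfpt(two_state_model(), [0], [])

    def test_raising_barrier_slows_escape(self, kt):
        from bindkin.synthdata.potentials import Potential

        def t_out(height):
            pot = Potential("binding_funnel",
                            {"wells": [(10.0, 2.0, 1.2)],
                             "bumps": [(16.0, height, 1.0)]},
                            domain=(5.0, 25.0))
            return analytic_mfpt(pot, 10.0, 16.0, 10.0)

        assert t_out(2.0) > t_out(1.0) > 0


class TestRates:
    def test_consistency_identity_exact(self):
        model = two_state_model(T=[[0.95, 0.05], [0.02, 0.98]])
        part = partition_two_state(model)
        res = rates(model, part, concentration=0.7)
        assert res.k_on * res.concentration * res.t_in == pytest.approx(1.0, rel=1e-14)
        assert res.k_off * res.t_out == pytest.approx(1.0, rel=1e-14)

    def test_kon_scales_inversely_with_concentration(self):
        model = two_state_model()
        part = partition_two_state(model)
        r1 = rates(model, part, concentration=0.7)
        r2 = rates(model, part, concentration=1.4)
        assert r1.t_in == r2.t_in
        assert r1.k_on == pytest.approx(2 * r2.k_on, rel=1e-14)

    def test_nonpositive_concentration_rejected(self):
        model = two_state_model()
        part = partition_two_state(model)
        with pytest.raises(ValueError, match="concentration"):
            rates(model, part, concentration=0.0)

    def test_summary_scales_units(self):
        model = two_state_model(T=[[1 - 1e-6, 1e-6], [0.5, 0.5]], lag=1.0)
        part = partition_two_state(model)
        s = rates(model, part, concentration=0.7).summary()
        assert s["t_out_unit"] in ("us", "ms")


class TestPublishedTable:
    """Arithmetic consistency of the published morphine/MOR kinetics rows."""

    def test_kon_equals_inverse_tin_times_c_within_1pct(self):
        _, _, rel = kon_consistency()
        assert rel.shape == (8,)
        assert np.all(rel < 0.01)

    def test_example_row(self):
        row = REFERENCE_TABLE[1]  # (+)-morphine, both aspartates charged
        assert row.t_in_ns == 63.79
        assert 1.0 / (row.t_in_ns * 0.70) == pytest.approx(0.02227, rel=0.01)

    def test_residence_ratio_8000fold(self):
        slow, fast = REFERENCE_TABLE[0], REFERENCE_TABLE[1]
        ratio = residence_time_ratio(slow, fast)
        assert float(f"{ratio:.1e}") == pytest.approx(8.0e3)

    def test_residence_ratio_2400fold(self):
        slow, fast = REFERENCE_TABLE[5], REFERENCE_TABLE[4]
        ratio = residence_time_ratio(slow, fast)
        assert float(f"{ratio:.1e}") == pytest.approx(2.4e3)

    def test_time_unit_round_trip(self):
        v, u = format_time_ns(REFERENCE_TABLE[0].t_out_ns)
        assert (v, u) == (pytest.approx(0.30), "s")


class TestBootstrapKinetics:
    def test_fixed_seed_reproducible(self, funnel_unbiased_data, kt):
        _, trajs, grid = funnel_unbiased_data
        kwargs = dict(lag=5, kt=kt, bulk_from=18.0, n_resamples=4, seed=2)
        a = bootstrap_kinetics(trajs, grid, **kwargs)
        b = bootstrap_kinetics(trajs, grid, **kwargs)
        assert np.array_equal(a["t_out"], b["t_out"])

    def test_single_resample_zero_width(self, funnel_unbiased_data, kt):
        _, trajs, grid = funnel_unbiased_data
        out = bootstrap_kinetics(trajs, grid, lag=5, kt=kt, bulk_from=18.0,
                                 n_resamples=1, seed=5)
        assert out["t_out"].size == 1

    def test_msm_residence_time_tracks_analytic_mfpt(
        self, funnel_unbiased_data, kt
    ):
        pot, trajs, grid = funnel_unbiased_data
        res, _, _ = kinetics_from_trajectories(trajs, grid, lag=5, kt=kt,
                                               bulk_from=18.0, method="barrier")
        truth = analytic_mfpt(pot, 10.0, 16.0, 10.0)
        assert res.t_out == pytest.approx(truth, rel=0.25)
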