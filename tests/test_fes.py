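"""Reweighting, region integration, standard-state bookkeeping, errors."""

import numpy as np
import pytest

from unbindkit.fes import (
    FESGrid,
    RegionBox,
    ThermoParams,
    ThermoResult,
    block_error,
    c_at_times,
    compute_c_of_t,
    free_energy_difference,
    kd_from_dg,
    reweight_fes,
    standard_binding_free_energy,
    volume_entropy_correction,
)
from unbindkit.metad import Hill

KCAL_PER_KT300 = 1.9872e-3 * 300.0


def _flat_fes(edges, values):
    return FESGrid(edges=edges, free_energy=values, kT=1.0, shifted=False)


class TestCOfT:
    def test_zero_bias_gives_zero_offset(self):
        hills = [Hill(center=(0.0,), widths=(0.2,), height=0.0, time=1.0)]
        state = compute_c_of_t(hills, [np.linspace(-1, 1, 21)], 10.0, 1.0)
        assert np.allclose(state.c, 0.0)
        assert np.allclose(c_at_times(state, [0.5, 2.0]), [0.0, 0.0])

    def test_spatially_constant_bias_returns_itself(self):
        # a gigantic width makes the hill constant over the grid
        hills = [
            Hill(center=(0.0,), widths=(1e9,), height=0.7, time=1.0),
            Hill(center=(0.0,), widths=(1e9,), height=0.4, time=2.0),
        ]
        state = compute_c_of_t(hills, [np.linspace(-1, 1, 21)], 10.0, 1.0)
        np.testing.assert_allclose(state.c, [0.7, 1.1], rtol=1e-9)

    def test_grid_refinement_converged(self, rng):
        hills = [
            Hill(center=(float(c),), widths=(0.3,), height=0.5, time=float(i))
            for i, c in enumerate(rng.uniform(-1, 1, size=30))
        ]
        coarse = compute_c_of_t(hills, [np.linspace(-1.5, 1.5, 41)], 10.0, 1.0)
        fine = compute_c_of_t(hills, [np.linspace(-1.5, 1.5, 161)], 10.0, 1.0)
        assert np.max(np.abs(coarse.c - fine.c)) < 0.1

    def test_offset_monotone_for_filling_bias(self, rng):
        hills = [
            Hill(center=(float(c),), widths=(0.3,), height=0.3, time=float(i))
            for i, c in enumerate(rng.uniform(-1, 1, size=40))
        ]
        state = compute_c_of_t(hills, [np.linspace(-1.5, 1.5, 61)], 10.0, 1.0)
        assert np.all(np.diff(state.c) > -1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            compute_c_of_t([], [], 10.0, 1.0)


class TestReweight:
    def test_unbiased_reduces_to_plain_histogram(self, rng):
        x = rng.normal(size=(4000, 1))
        edges = [np.linspace(-3, 3, 25)]
        fes = reweight_fes(x, np.zeros(4000), np.zeros(4000), edges, 1.0)
        cnt, _ = np.histogram(x[:, 0], bins=edges[0])
        f_plain = -np.log(cnt / cnt.sum() / np.diff(edges[0]))
        f_plain -= f_plain[np.isfinite(f_plain)].min()
        m = cnt > 0
        np.testing.assert_allclose(fes.free_energy[m], f_plain[m], atol=1e-12)

    def test_unit_rescaling_leaves_f_over_kt_unchanged(self, rng):
        x = rng.normal(size=(2000, 1))
        v = rng.uniform(0, 2, size=2000)
        c = np.full(2000, 0.5)
        edges = [np.linspace(-3, 3, 15)]
        f1 = reweight_fes(x, v, c, edges, kT=1.0)
        f2 = reweight_fes(x, 2.5 * v, 2.5 * c, edges, kT=2.5)
        m = np.isfinite(f1.free_energy)
        np.testing.assert_allclose(
            f1.free_energy[m], f2.free_energy[m] / 2.5, rtol=1e-10
        )

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            reweight_fes(
                np.empty((0, 1)), np.empty(0), np.empty(0),
                [np.linspace(0, 1, 5)], 1.0,
            )


class TestFreeEnergyDifference:
    def test_symmetric_regions_give_zero(self):
        edges = [np.linspace(-2, 2, 41), np.linspace(-2, 2, 41)]
        cx = 0.5 * (edges[0][:-1] + edges[0][1:])
        X, Y = np.meshgrid(cx, cx, indexing="ij")
        f = X**2 + Y**2  # symmetric under x -> -x
        fes = _flat_fes(edges, f)
        left = RegionBox(intervals=((-1.5, -0.5), (-1.0, 1.0)), label="L")
        right = RegionBox(intervals=((0.5, 1.5), (-1.0, 1.0)), label="R")
        assert free_energy_difference(fes, left, right) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_level_closed_form(self):
        edges = [np.linspace(0, 2, 21), np.linspace(0, 2, 21)]
        f = np.zeros((20, 20))
        f[10:, :] = 3.0  # unbound shelf at +3 kT, equal area
        fes = _flat_fes(edges, f)
        bound = RegionBox(intervals=((0.0, 1.0), (0.0, 2.0)), label="b")
        unbound = RegionBox(intervals=((1.0, 2.0), (0.0, 2.0)), label="u")
        assert free_energy_difference(fes, bound, unbound) == pytest.approx(
            -3.0, abs=1e-12
        )

    def test_flat_plateau_region_shrink_is_entropic(self):
        edges = [np.linspace(0, 4, 81), np.linspace(0, 1, 11)]
        fes = _flat_fes(edges, np.zeros((80, 10)))
        bound = RegionBox(intervals=((0.0, 1.0), (0.0, 1.0)), label="b")
        u_wide = RegionBox(intervals=((1.0, 4.0), (0.0, 1.0)), label="u")
        u_half = RegionBox(intervals=((1.0, 2.5), (0.0, 1.0)), label="u2")
        dg_wide = free_energy_difference(fes, bound, u_wide)
        dg_half = free_energy_difference(fes, bound, u_half)
        assert dg_half - dg_wide == pytest.approx(-np.log(3.0 / 1.5),
                                                  abs=1e-12)

    def test_empty_region_names_the_region(self):
        edges = [np.linspace(0, 1, 11), np.linspace(0, 1, 11)]
        f = np.zeros((10, 10))
        f[5:, :] = np.inf  # never visited
        fes = _flat_fes(edges, f)
        bound = RegionBox(intervals=((0.0, 0.5), (0.0, 1.0)), label="bound")
        ghost = RegionBox(intervals=((0.5, 1.0), (0.0, 1.0)), label="ghost")
        with pytest.raises(ValueError, match="ghost"):
            free_energy_difference(fes, bound, ghost)


class TestStandardState:
    def test_protein_scale_entropy_correction(self):
        """Restraint sphere of 28 A around a 48300 A^3 protein at 300 K."""
        tds = volume_entropy_correction(ThermoParams())
        assert round(tds, 1) == 1.9

    def test_accessible_volume_equal_standard_is_zero(self):
        rho = (3.0 * 1660.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        p = ThermoParams(restraint_radius=rho, protein_volume=0.0)
        assert volume_entropy_correction(p) == pytest.approx(0.0, abs=1e-9)

    def test_e_fold_volume_gives_rt(self):
        rho = (3.0 * np.e * 1660.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        p = ThermoParams(restraint_radius=rho, protein_volume=0.0)
        assert volume_entropy_correction(p) == pytest.approx(
            KCAL_PER_KT300, rel=1e-9
        )

    def test_vanishing_accessible_volume_rejected(self):
        with pytest.raises(ValueError, match="accessible"):
            volume_entropy_correction(
                ThermoParams(restraint_radius=5.0, protein_volume=1e6)
            )

    @pytest.mark.parametrize(
        "dg_metad,tds,expected",
        [(-3.3, 1.9, -5.2), (-2.8, 1.9, -4.7), (0.7, 0.0, 0.7)],
    )
    def test_binding_free_energy_bookkeeping(self, dg_metad, tds, expected):
        assert standard_binding_free_energy(dg_metad, tds) == pytest.approx(
            expected
        )

    def test_kd_identities(self):
        assert kd_from_dg(0.0) == pytest.approx(1.0)
        assert kd_from_dg(-KCAL_PER_KT300 * np.log(10.0)) == pytest.approx(0.1)
        # -5.2 kcal/mol at 300 K sits in the 0.2 mM range
        kd_mM = 1e3 * kd_from_dg(-5.2)
        assert float(f"{kd_mM:.1g}") == 0.2

    def test_thermo_result_consistency_enforced(self):
        with pytest.raises(ValueError):
            ThermoResult(dg_metad=-3.3, tds=1.9, dg_b=-5.0, kd_mM=0.1)

    def test_inconsistent_standard_volume_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ThermoParams(standard_volume=2000.0)


class TestConvergenceSeries:
    def test_final_checkpoint_equals_full_data_estimate(self, rng):
        from unbindkit.fes import ReweightState, dg_convergence

        n = 5000
        x = np.concatenate(
            [rng.normal(-1.0, 0.25, n // 2), rng.normal(1.0, 0.25, n - n // 2)]
        )
        rng.shuffle(x)
        t = np.linspace(0.01, 100.0, n)
        edges = [np.linspace(-2, 2, 33)]
        state = ReweightState(times=np.empty(0), c=np.empty(0),
                              bias_factor=10.0, kT=1.0)
        bound = RegionBox(intervals=((-1.8, -0.2),), label="b")
        unbound = RegionBox(intervals=((0.2, 1.8),), label="u")
        series = dg_convergence(
            x[:, None], t, np.zeros(n), state, edges, bound, unbound, 1.0,
            checkpoints=[30.0, 60.0, 100.0], discard_fraction=0.1,
        )
        keep = t >= 0.1 * t[-1]
        full = reweight_fes(x[keep, None], np.zeros(keep.sum()),
                            np.zeros(keep.sum()), edges, 1.0)
        dg_full = free_energy_difference(full, bound, unbound)
        assert series[-1] == pytest.approx(dg_full, abs=1e-12)
        assert np.all(np.isfinite(series))

    def test_decreasing_checkpoints_rejected(self):
        from unbindkit.fes import ReweightState, dg_convergence

        state = ReweightState(times=np.empty(0), c=np.empty(0),
                              bias_factor=10.0, kT=1.0)
        with pytest.raises(ValueError, match="increasing"):
            dg_convergence(
                np.zeros((10, 1)), np.arange(10.0), np.zeros(10), state,
                [np.linspace(-1, 1, 5)],
                RegionBox(intervals=((-1, 0),)),
                RegionBox(intervals=((0, 1),)),
                1.0, checkpoints=[5.0, 2.0],
            )


class TestBlockError:
    def test_constant_series_is_zero(self):
        ba = block_error(np.full(256, 3.14))
        assert ba.error == 0.0

    def test_iid_flat_in_block_size(self, rng):
        errs = []
        for _ in range(100):
            ba = block_error(rng.normal(size=512), block_sizes=[1, 4, 16, 64])
            errs.append(ba.errors)
        mean_err = np.mean(errs, axis=0)
        assert mean_err.max() / mean_err.min() < 1.2

    def test_ar1_plateaus_at_known_error(self, rng):
        phi, n = 0.9, 20_000
        tau_int = (1.0 + phi) / (2.0 * (1.0 - phi))
        plateaus = []
        for _ in range(20):
            x = np.empty(n)
            x[0] = rng.normal()
            eps = rng.normal(size=n)
            for i in range(1, n):
                x[i] = phi * x[i - 1] + eps[i]
            sigma = np.std(x)
            expected = sigma * np.sqrt(2.0 * tau_int / n)
            ba = block_error(x, block_sizes=[1, 16, 64, 256, 1024])
            assert ba.errors[0] < ba.error  # grows from the naive value
            plateaus.append(ba.error / expected)
        assert np.mean(plateaus) == pytest.approx(1.0, abs=0.25)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            block_error([1.0, 2.0, 3.0], block_sizes=[2])
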