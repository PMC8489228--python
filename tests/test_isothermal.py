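import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoquant.fit_engine import FLAG_LOW_AMPLITUDE, FLAG_NO_SHIFT
from thermoquant.io_formats import TitrationTable
from thermoquant.isothermal import (fit_isothermal_kd, fit_tm_shift,
                                    fluorescence_fit, isothermal_model_1to1,
                                    isothermal_model_1to2, predict_tm_shift,
                                    solve_lfree, solve_lfree_two_site,
                                    unfolded_fraction_at)
from thermoquant.preprocess import restrict_range
from thermoquant.synthetic import (LigandSeriesScenario, dilution_series,
                                   gen_ligand_series)


def lfree_bisection(ltot, ptot, ku, kd, iters=200):
    """Independent bisection oracle for the 1:1 free-ligand mass balance.

    The residual L + bound(L) - Ltot is monotone in L, so the root is
    bracketed on [0, Ltot]; 200 halvings reach machine precision.
    """
    lo, hi = 0.0, ltot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        bound = (ptot / (1 + ku + mid / kd)) * mid / kd
        if mid + bound < ltot:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSolveLfree:
    def test_zero_ligand(self):
        assert solve_lfree(0.0, 15e-6, 1.0, 1.3e-6) == 0.0

    def test_reference_value(self):
        lf = solve_lfree(150e-6, 15e-6, 1.0, 1.3e-6)
        assert lf == pytest.approx(135.3e-6, rel=1e-3)
        assert lf == pytest.approx(lfree_bisection(150e-6, 15e-6, 1.0, 1.3e-6),
                                   rel=1e-10)

    def test_dilute_protein_limit(self):
        assert solve_lfree(1e-4, 1e-12, 1.0, 1e-6) == pytest.approx(1e-4, rel=1e-6)

    def test_mass_balance_residual(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            ltot = 10 ** rng.uniform(-8, -3)
            ptot = 10 ** rng.uniform(-8, -4)
            ku = 10 ** rng.uniform(-2, 2)
            kd = 10 ** rng.uniform(-9, -4)
            lf = solve_lfree(ltot, ptot, ku, kd)
            assert 0 <= lf <= ltot
            bound = (ptot / (1 + ku + lf / kd)) * lf / kd
            assert abs(lf + bound - ltot) < 1e-12 * max(ltot, 1e-30)

    @given(st.floats(-8, -3), st.floats(-8, -4), st.floats(-2, 2), st.floats(-9, -4))
    @settings(derandomize=True, max_examples=100)
    def test_quadratic_matches_fixed_point(self, l_ltot, l_ptot, l_ku, l_kd):
        ltot, ptot, ku, kd = 10 ** l_ltot, 10 ** l_ptot, 10 ** l_ku, 10 ** l_kd
        lf = solve_lfree(ltot, ptot, ku, kd)
        assert lf == pytest.approx(lfree_bisection(ltot, ptot, ku, kd),
                                   rel=1e-10, abs=1e-25)


class TestIsothermalModels:
    def test_no_ligand_gives_ku_fraction(self):
        assert isothermal_model_1to1(0.0, 15e-6, 1.0, 2e-6) == pytest.approx(0.5)

    def test_reference_value(self):
        fu = isothermal_model_1to1(150e-6, 15e-6, 1.0, 1.3e-6)
        assert fu == pytest.approx(0.0094, abs=2e-4)

    def test_weak_binding_limit(self):
        fu = isothermal_model_1to1(1e-4, 15e-6, 1.0, 1e3)
        assert fu == pytest.approx(0.5, rel=1e-6)

    def test_monotone_decreasing_in_ligand(self):
        lig = dilution_series(150e-6, 1.5, 16)[::-1]
        fu = np.array([isothermal_model_1to1(L, 15e-6, 1.0, 2e-6) for L in lig])
        assert np.all(np.diff(fu) < 0)

    def test_two_site_reduces_to_one_site(self):
        for L in (0.0, 1e-6, 1e-5, 1e-4):
            one = isothermal_model_1to1(L, 15e-6, 1.0, 2e-6)
            two = isothermal_model_1to2(L, 15e-6, 1.0, 2e-6, 1e3)
            assert two == pytest.approx(one, abs=1e-6)

    def test_identical_sites_identity(self):
        kd = 2e-6
        for L in (1e-6, 1e-5, 1e-4):
            lf = solve_lfree_two_site(L, 15e-6, 1.0, kd, kd)
            expected = 1.0 / (1.0 + (1 + lf / kd) ** 2)
            assert isothermal_model_1to2(L, 15e-6, 1.0, kd, kd) == pytest.approx(
                expected, rel=1e-9)

    def test_two_site_bisection_vs_grid_scan(self):
        ptot, ku, kd1, kd2 = 15e-6, 0.8, 1e-6, 5e-6
        for ltot in (1e-6, 2e-5, 1.2e-4):
            lf = solve_lfree_two_site(ltot, ptot, ku, kd1, kd2)
            grid = np.linspace(0, ltot, 10 ** 6)
            q = (1 + grid / kd1) * (1 + grid / kd2)
            f = ptot / (ku + q)
            resid = grid + f * (grid / kd1 * (1 + grid / kd2)
                                + grid / kd2 * (1 + grid / kd1)) - ltot
            best = grid[np.argmin(np.abs(resid))]
            assert lf == pytest.approx(best, abs=2 * ltot / 10 ** 6)


class TestFluorescenceFit:
    def test_tm_obs_increases_with_ligand(self, ligand_series):
        scenario, mcs = ligand_series
        ds = fluorescence_fit(restrict_range(mcs, 303.15, 329.15), "local",
                              scenario.ptot_M)
        order = np.argsort(ds.ligand_conc_M)
        assert np.all(np.diff(ds.tm_obs[order]) > -0.05)
        assert ds.tm_obs[order][-1] - ds.tm_obs[order][0] > 3.0

    def test_local_vs_global_agree_noiseless(self):
        scenario = LigandSeriesScenario(noise_sd=0.0, n_concentrations=6, seed=0)
        mcs = gen_ligand_series(scenario)
        local = fluorescence_fit(mcs, "local", scenario.ptot_M)
        glob = fluorescence_fit(mcs, "global", scenario.ptot_M)
        np.testing.assert_allclose(local.tm_obs, glob.tm_obs, atol=0.05)

    def test_zero_ligand_matches_free_protein(self):
        scenario = LigandSeriesScenario(noise_sd=0.0, n_concentrations=4,
                                        include_zero=True, seed=0)
        mcs = gen_ligand_series(scenario)
        ds = fluorescence_fit(mcs, "local", scenario.ptot_M)
        i0 = int(np.argmin(ds.ligand_conc_M))
        assert ds.ligand_conc_M[i0] == 0.0
        assert ds.tm_obs[i0] == pytest.approx(scenario.tm0_K, abs=0.1)

    def test_unannotated_well_rejected(self, small_plate):
        _, plate = small_plate
        with pytest.raises(ValueError, match="without ligand annotation"):
            fluorescence_fit(plate, "local", 15e-6)


@pytest.fixture(scope="module")
def dataset(ligand_series):
    scenario, mcs = ligand_series
    return scenario, fluorescence_fit(restrict_range(mcs, 303.15, 329.15),
                                      "local", scenario.ptot_M)


class TestUnfoldedFractionAt:
    def test_half_unfolded_at_each_tm_obs(self, dataset):
        _, ds = dataset
        i = 3
        table = unfolded_fraction_at(ds, float(ds.tm_obs[i]))
        match = table.response[np.argmin(np.abs(table.ligand_conc_M
                                                - ds.ligand_conc_M[i]))]
        assert match == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_temperature(self, dataset):
        _, ds = dataset
        low = unfolded_fraction_at(ds, 310.15)
        high = unfolded_fraction_at(ds, 318.15)
        assert np.all(high.response > low.response)

    def test_outside_range_rejected(self, dataset):
        _, ds = dataset
        with pytest.raises(ValueError, match="outside fitted range"):
            unfolded_fraction_at(ds, 400.0)

    def test_wide_dynamic_range_near_free_tm(self, dataset):
        scenario, ds = dataset
        table = unfolded_fraction_at(ds, 317.15)  # 44 C, ~2 K above free Tm
        assert np.ptp(table.response) > 0.5
        order = np.argsort(table.ligand_conc_M)
        assert table.response[order][0] > table.response[order][-1]


class TestFitIsothermalKd:
    def test_noiseless_recovery(self):
        lig = dilution_series(150e-6, 1.5, 16)
        ku, kd, ptot = 1.2, 2e-6, 15e-6
        fu = np.array([isothermal_model_1to1(L, ptot, ku, kd) for L in lig])
        fit = fit_isothermal_kd(TitrationTable(lig, fu), ptot)
        assert fit.derived["Kd_M"][0] == pytest.approx(kd, rel=1e-4)
        assert fit.derived["Ku"][0] == pytest.approx(ku, rel=1e-4)

    def test_noiseless_recovery_two_site(self):
        lig = dilution_series(150e-6, 1.5, 16)
        ku, kd1, kd2, ptot = 1.0, 1e-6, 2e-5, 15e-6
        fu = np.array([isothermal_model_1to2(L, ptot, ku, kd1, kd2) for L in lig])
        fit = fit_isothermal_kd(TitrationTable(lig, fu), ptot, model="1to2")
        kds = sorted([fit.derived["Kd_M"][0], fit.derived["Kd2_M"][0]])
        assert kds[0] == pytest.approx(kd1, rel=0.05)

    def test_flat_table_warns_low_amplitude(self):
        lig = dilution_series(150e-6, 1.5, 8)
        with pytest.warns(UserWarning, match="LOW_AMPLITUDE"):
            fit = fit_isothermal_kd(TitrationTable(lig, np.full(8, 0.5)), 15e-6)
        assert FLAG_LOW_AMPLITUDE in fit.flags

    def test_end_to_end_recovery(self, ligand_series):
        scenario, mcs = ligand_series
        ds = fluorescence_fit(restrict_range(mcs, 303.15, 329.15), "local",
                              scenario.ptot_M)
        table = unfolded_fraction_at(ds, 317.15)
        fit = fit_isothermal_kd(table, scenario.ptot_M)
        assert fit.derived["Kd_M"][0] == pytest.approx(scenario.kd_M, rel=0.3)


class TestTmShift:
    def test_zero_ligand_predicts_tm0(self):
        assert predict_tm_shift(0.0, 328.15, 4e5, 1.3e-6) == 328.15

    def test_reference_value_vs_bisection(self):
        tm = predict_tm_shift(150e-6, 328.15, 4e5, 1.3e-6)
        assert tm == pytest.approx(339.1, abs=0.1)
        # independent bisection on the melting condition
        from thermoquant.dsf_models import R
        lo, hi = 328.15, 378.15
        rhs = math.log(1 + 150e-6 / 1.3e-6)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if -4e5 * (1 - mid / 328.15) / (R * mid) < rhs:
                lo = mid
            else:
                hi = mid
        assert tm == pytest.approx(lo, abs=1e-6)

    def test_parameter_recovery(self):
        lig = dilution_series(150e-6, 1.5, 16)
        kd, tm0, dhu = 2e-6, 315.15, 4e5
        rng = np.random.default_rng(4)
        tm_obs = predict_tm_shift(lig, tm0, dhu, kd) + rng.normal(0, 0.05, 16)
        fit = fit_tm_shift(lig, tm_obs, dhu, tm0)
        assert fit.derived["Kd_M"][0] == pytest.approx(kd, rel=0.25)

    def test_no_shift_warns(self):
        lig = dilution_series(1e-6, 2.0, 6)
        with pytest.warns(UserWarning, match="NO_SHIFT"):
            fit = fit_tm_shift(lig, np.full(6, 328.15), 4e5, 328.15)
        assert FLAG_NO_SHIFT in fit.flags

    def test_agreement_with_isothermal_route(self, ligand_series):
        """The two Kd routes are different approximations; they agree within 2x."""
        scenario, mcs = ligand_series
        ds = fluorescence_fit(restrict_range(mcs, 303.15, 329.15), "local",
                              scenario.ptot_M)
        iso = fit_isothermal_kd(unfolded_fraction_at(ds, 317.15), scenario.ptot_M)
        i0 = int(np.argmin(ds.ligand_conc_M))
        shift = fit_tm_shift(ds.ligand_conc_M, ds.tm_obs,
                             dHu=float(ds.dH_obs[i0]), tm0_K=float(ds.tm_obs[i0]))
        ratio = shift.derived["Kd_M"][0] / iso.derived["Kd_M"][0]
        assert 0.5 <= ratio <= 2.0
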