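import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoquant.dsf_models import (R, dG_at, fit_melt_curve,
                                    fractions_three_state, fu_empirical,
                                    fu_irreversible, fu_two_state,
                                    rank_conditions, rate_irreversible,
                                    signal_two_state, tonset,
                                    tonset_closed_form)
from thermoquant.fit_engine import FLAG_CONSTANT, ModelFit
from thermoquant.io_formats import MeltCurveSet
from thermoquant.synthetic import gen_dsf_plate, ph_screen_scenario

GRID = np.arange(293.15, 363.15, 1.0)


class TestTwoStateEquilibrium:
    def test_half_unfolded_at_tm(self):
        assert fu_two_state(328.15, 4e5, 328.15) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_value(self):
        # independent evaluation of the Gibbs-Helmholtz chain
        dg = 4e5 * (1 - 323.15 / 328.15)
        ku = math.exp(-dg / (R * 323.15))
        expected = ku / (1 + ku)
        assert expected == pytest.approx(0.0937, abs=2e-4)
        assert fu_two_state(323.15, 4e5, 328.15) == pytest.approx(expected, rel=1e-12)

    def test_step_limit_at_large_enthalpy(self):
        # fu(Tm +/- 1 K) -> {0, 1} as dHu grows: exp(-dHu/(R*T*Tm)) per Kelvin
        assert fu_two_state(327.15, 5e6, 328.15) < 5e-3
        assert fu_two_state(329.15, 5e6, 328.15) > 1 - 5e-3
        assert fu_two_state(327.15, 5e7, 328.15) < 1e-6
        assert fu_two_state(329.15, 5e7, 328.15) > 1 - 1e-6

    @given(st.floats(5e4, 1.5e6), st.floats(300.0, 350.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_temperature(self, dhu, tm):
        fu = fu_two_state(GRID, dhu, tm)
        assert np.all(np.diff(fu) >= 0)

    def test_brute_force_equivalence(self):
        """fu computed through Ku/(1+Ku) with a separately coded dG matches."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            dhu = rng.uniform(5e4, 1.5e6)
            tm = rng.uniform(300, 350)
            t = rng.uniform(280, 370)
            dg = dhu - dhu * t / tm  # independently expanded form
            ku = math.exp(-dg / (R * t))
            assert fu_two_state(t, dhu, tm) == pytest.approx(ku / (1 + ku), rel=1e-12)


class TestSignalTwoState:
    PARAMS = {"dHu": 4e5, "Tm": 328.15, "bN": 0.8, "kN": -0.001,
              "bU": 1.2, "kU": -0.0025}

    def test_native_baseline_in_folded_region(self):
        t = np.array([295.15, 300.15])
        s = signal_two_state(t, self.PARAMS, 295.15)
        native = self.PARAMS["bN"] + self.PARAMS["kN"] * (t - 295.15)
        np.testing.assert_allclose(s, native, atol=1e-6)

    def test_unit_baselines_reduce_to_fu(self):
        p = {"dHu": 4e5, "Tm": 328.15, "bN": 0.0, "kN": 0.0, "bU": 1.0, "kU": 0.0}
        np.testing.assert_allclose(signal_two_state(GRID, p, GRID[0]),
                                   fu_two_state(GRID, 4e5, 328.15))

    def test_baseline_recovery_noiseless(self):
        t = GRID
        y = signal_two_state(t, self.PARAMS, t[0])
        mcs = MeltCurveSet(t, y[None, :], ["A1"])
        fit = fit_melt_curve(mcs, "A1", "two_state_eq")
        for name in ("bN", "kN", "bU", "kU"):
            assert fit.params[name] == pytest.approx(self.PARAMS[name],
                                                     rel=0.01, abs=1e-5)


class TestIrreversible:
    def test_rate_is_unity_at_tf(self):
        assert rate_irreversible(330.0, 3e5, 330.0) == pytest.approx(1.0)

    def test_frozen_limit(self):
        fu = fu_irreversible(GRID, 1.5e6, 500.0)
        assert np.all(fu < 1e-8)

    def test_starts_at_zero_and_monotone(self):
        fu = fu_irreversible(GRID, 3e5, 330.0)
        assert fu[0] == 0.0
        assert np.all(np.diff(fu) >= 0)

    def test_refinement_oracle(self):
        # default refinement is within 1e-5 of a 10x finer trapezoid grid
        coarse = fu_irreversible(GRID, 3e5, 330.0)
        fine = fu_irreversible(GRID, 3e5, 330.0, refine=300)
        assert np.max(np.abs(coarse - fine)) < 1e-5

    def test_faster_scan_shifts_midpoint_up(self):
        t_half = []
        for v in (1.0, 2.0):
            fu = fu_irreversible(GRID, 3e5, 330.0, scan_rate=v)
            t_half.append(np.interp(0.5, fu, GRID))
        assert t_half[1] > t_half[0]


class TestThreeState:
    def test_reduces_to_two_state_when_k2_absent(self):
        fn, fi, fu = fractions_three_state(GRID, 4e5, 320.15, 4e5, 500.0)
        np.testing.assert_allclose(fi, fu_two_state(GRID, 4e5, 320.15), atol=1e-9)
        assert np.all(fu < 1e-9)

    def test_equal_populations_at_tm1(self):
        fn, fi, fu = fractions_three_state(320.15, 4e5, 320.15, 4e5, 500.0)
        assert fn == pytest.approx(0.5, abs=1e-9)
        assert fi == pytest.approx(0.5, abs=1e-9)

    @given(st.floats(1e5, 8e5), st.floats(305.0, 330.0),
           st.floats(1e5, 8e5), st.floats(330.0, 360.0))
    @settings(derandomize=True, max_examples=50)
    def test_fractions_sum_to_one(self, dh1, tm1, dh2, tm2):
        fn, fi, fu = fractions_three_state(GRID, dh1, tm1, dh2, tm2)
        np.testing.assert_allclose(fn + fi + fu, 1.0, atol=1e-12)


class TestEmpirical:
    def test_half_unfolded_at_tm(self):
        assert fu_empirical(328.15, 328.15, 2.0) == 0.5

    def test_sharp_limit(self):
        assert fu_empirical(327.15, 328.15, 1e-3) < 1e-12
        assert fu_empirical(329.15, 328.15, 1e-3) > 1 - 1e-12

    def test_matches_thermodynamic_model_near_tm(self):
        """Logistic with s = R*Tm^2/dHu is the first-order expansion at Tm."""
        dhu, tm = 4e5, 328.15
        s = R * tm ** 2 / dhu
        t = np.linspace(tm - 2, tm + 2, 81)
        diff = np.abs(fu_empirical(t, tm, s) - fu_two_state(t, dhu, tm))
        assert np.max(diff) < 0.01


class TestTonset:
    def test_closed_form_value(self):
        t_on = tonset({"dHu": 4e5, "Tm": 328.15})
        assert t_on == pytest.approx(318.18, abs=0.01)
        assert t_on == pytest.approx(tonset_closed_form(4e5, 328.15), abs=1e-6)

    def test_defining_identity(self):
        t_on = tonset({"dHu": 4e5, "Tm": 328.15})
        assert fu_two_state(t_on, 4e5, 328.15) == pytest.approx(0.01, abs=1e-9)

    @given(st.floats(1e5, 1.5e6), st.floats(300.0, 350.0))
    @settings(derandomize=True, max_examples=50)
    def test_onset_below_tm(self, dhu, tm):
        assert tonset({"dHu": dhu, "Tm": tm}) < tm

    def test_empirical_variant(self):
        t_on = tonset({"Tm": 328.15, "s": 2.0}, "empirical_two_state")
        assert fu_empirical(t_on, 328.15, 2.0) == pytest.approx(0.01, abs=1e-9)


class TestFreeEnergy:
    def test_zero_at_tm(self):
        assert dG_at(328.15, 4e5, 328.15) == pytest.approx(0.0, abs=1e-9)

    def test_value_at_25c(self):
        assert dG_at(298.15, 4e5, 328.15) == pytest.approx(36.57e3, rel=1e-3)

    def test_decreasing_in_temperature(self):
        t = np.linspace(298.15, 328.15, 50)
        dg = dG_at(t, 4e5, 328.15)
        assert np.all(np.diff(dg) < 0)


class TestFitMeltCurve:
    @pytest.mark.parametrize("model,tm_tol", [("two_state_eq", 0.2),
                                              ("empirical_two_state", 0.5)])
    def test_plate_recovery(self, small_plate, model, tm_tol):
        scenario, plate = small_plate
        errors = []
        for well in plate.well_ids:
            fit = fit_melt_curve(plate, well, model)
            assert fit.converged
            errors.append(abs(fit.params["Tm"] - scenario.wells[well][1]["Tm"]))
        assert np.median(errors) < tm_tol

    def test_enthalpy_recovery(self, small_plate):
        scenario, plate = small_plate
        rel = []
        for well in plate.well_ids:
            fit = fit_melt_curve(plate, well, "two_state_eq")
            truth = scenario.wells[well][1]["dHu"]
            rel.append(abs(fit.params["dHu"] - truth) / truth)
        assert np.median(rel) < 0.05

    def test_flat_well_flagged(self):
        mcs = MeltCurveSet(GRID, np.full((1, GRID.size), 2.0), ["A1"])
        fit = fit_melt_curve(mcs, "A1")
        assert FLAG_CONSTANT in fit.flags

    def test_unknown_model_rejected(self, small_plate):
        _, plate = small_plate
        with pytest.raises(ValueError, match="unknown model"):
            fit_melt_curve(plate, plate.well_ids[0], "four_state")


class TestRanking:
    @staticmethod
    def _fit(tm, dhu=4e5, flags=()):
        f = ModelFit(model="two_state_eq", params={"Tm": tm, "dHu": dhu},
                     std_errors={"Tm": 0.1, "dHu": 1e4}, covariance=None,
                     residual_rms=0.01, converged=True, n_points=70)
        f.flags |= set(flags)
        return f

    def test_descending_order(self):
        fits = [("w1", self._fit(328.0)), ("w2", self._fit(335.0)),
                ("w3", self._fit(320.0))]
        ranked = rank_conditions(fits, "Tm")
        assert list(ranked.fit_id) == ["w2", "w1", "w3"]

    def test_flagged_fit_listed_separately(self):
        fits = [("w1", self._fit(328.0)), ("w2", self._fit(335.0, flags=["NOT_CONVERGED"]))]
        ranked = rank_conditions(fits, "Tm")
        main = ranked[ranked.section == "ranked"]
        flagged = ranked[ranked.section == "flagged"]
        assert list(main.fit_id) == ["w1"]
        assert list(flagged.fit_id) == ["w2"]

    def test_ph_screen_order_matches_generator(self):
        scenario = ph_screen_scenario(seed=5)
        plate = gen_dsf_plate(scenario)
        fits = [(w, fit_melt_curve(plate, w)) for w in plate.well_ids]
        ranked = rank_conditions(fits, "Tm")
        # generator Tm increases with condition index -> ranking is the reverse
        expected = list(reversed(plate.well_ids))
        assert list(ranked[ranked.section == "ranked"].fit_id) == expected

    def test_dg25_unavailable_for_empirical(self):
        emp = ModelFit(model="empirical_two_state", params={"Tm": 328.0, "s": 2.0},
                       std_errors={"Tm": 0.1, "s": 0.1}, covariance=None,
                       residual_rms=0.01, converged=True, n_points=70)
        with pytest.raises(ValueError, match="dG25"):
            rank_conditions([("w1", emp)], "dG25")

    def test_ranking_by_dg25_and_tonset(self):
        fits = [("w1", self._fit(328.0)), ("w2", self._fit(335.0))]
        for criterion in ("dG25", "Tonset"):
            ranked = rank_conditions(fits, criterion)
            assert list(ranked.fit_id) == ["w2", "w1"]
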