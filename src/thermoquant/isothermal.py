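"""Isothermal and Tm-shift estimation of ligand affinity from thermal-shift data.

The isothermal route has two steps.  First every melting curve of a ligand
titration is fitted with an apparent two-state model (dCp = 0), giving a
ligand-dependent unfolding constant Ku_obs(T) per concentration
(:func:`fluorescence_fit`).  Second, the unfolded fractions evaluated at one
fixed temperature Ti (chosen near the Tm of the free protein, where the
dynamic range of fu is largest) are fitted against total ligand concentration
with a coupled folding-binding model in which the ligand binds only the
native state (:func:`fit_isothermal_kd`):

    fu = Ku / (Ku + 1 + Lfree/Kd)                       (1:1)
    fu = Ku / (Ku + (1 + Lfree/Kd1)(1 + Lfree/Kd2))     (1:2)

with the free-ligand concentration solved from mass balance at each point.
A stabilizing ligand lowers fu at fixed temperature, so fu decreases with
concentration.

The Tm-shift alternative skips the isothermal step: assuming Lfree = Ltot,
the observed melting temperature satisfies Ku(Tm_obs) = 1 + Ltot/Kd, i.e.

    -dHu (1 - T/Tm0) / (R T) = ln(1 + Ltot/Kd),

which is solved for T per concentration and least-squares fitted to the
observed Tm values.  Kd is fitted on a log10 scale in both routes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import fit_engine
from .dsf_models import R, fu_two_state, signal_two_state
from .fit_engine import (FLAG_LOW_AMPLITUDE, FLAG_NO_SHIFT, FitBounds,
                         ModelFit, initial_guess_two_state, nls_fit)
from .io_formats import MeltCurveSet, TitrationTable

KD_LOG_BOUNDS = (-12.0, -1.0)  # log10 Kd in M: picomolar to 100 mM


@dataclass
class IsothermalDataset:
    """Apparent two-state parameters per ligand concentration.

    ``dH_obs`` (J/mol) and ``tm_obs`` (K) define Ku_obs(T) for each
    concentration; ``t_range_K`` records the fitted temperature range so the
    isothermal temperature can be validated against it.
    """

    ligand_conc_M: np.ndarray
    dH_obs: np.ndarray
    tm_obs: np.ndarray
    ptot_M: float
    t_range_K: tuple[float, float]
    fits: list[ModelFit] = field(default_factory=list)
    dCp: float = 0.0

    def __post_init__(self):
        self.ligand_conc_M = np.asarray(self.ligand_conc_M, dtype=float)
        self.dH_obs = np.asarray(self.dH_obs, dtype=float)
        self.tm_obs = np.asarray(self.tm_obs, dtype=float)
        if not (self.ligand_conc_M.size == self.dH_obs.size == self.tm_obs.size):
            raise ValueError("one (dH_obs, Tm_obs) pair per concentration required")
        if self.ptot_M <= 0:
            raise ValueError("protein concentration must be > 0")


@dataclass
class TmShiftParams:
    tm0_K: float
    dHu: float
    kd_M: float

    def __post_init__(self):
        if self.kd_M <= 0:
            raise ValueError("Kd must be > 0")


# ---------------------------------------------------------------------------
# step 1: per-concentration melt fits
# ---------------------------------------------------------------------------

def fluorescence_fit(mcs: MeltCurveSet, mode: str = "local",
                     ptot_M: float = 1e-6, dCp: float = 0.0) -> IsothermalDataset:
    """Fit every annotated well with the apparent two-state model.

    ``mode="local"`` fits each curve independently; ``mode="global"``
    shares the baseline slopes (kN, kU) across all curves while keeping
    per-curve dH_obs, Tm_obs and baseline intercepts.  The heat-capacity
    change ``dCp`` is held fixed (0 by default, the usual assumption for
    thermal-shift titrations).  Wells whose fit does not converge are
    excluded (with a warning).
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    ligs = mcs.annotations["ligand_conc_M"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ligs)):
        missing = [w for w, ok in zip(mcs.well_ids, np.isfinite(ligs)) if not ok]
        raise ValueError(f"wells without ligand annotation: {missing}")
    t = mcs.temperature_K
    tref = float(t[0])

    if mode == "local":
        keep, fits = [], []
        for i, well in enumerate(mcs.well_ids):
            fit = nls_fit(lambda x, p: signal_two_state(x, p, tref, dCp),
                          t, mcs.signals[i], initial_guess_two_state(t, mcs.signals[i]),
                          _two_state_bounds(t), model_name="two_state_eq")
            if not fit.converged:
                warnings.warn(f"well {well!r} did not converge; excluded", stacklevel=2)
                continue
            keep.append(i)
            fits.append(fit)
        if not keep:
            raise ValueError("no well converged")
        return IsothermalDataset(
            ligs[keep],
            np.array([f.params["dHu"] for f in fits]),
            np.array([f.params["Tm"] for f in fits]),
            ptot_M, (float(t[0]), float(t[-1])), fits, dCp)

    return _global_fluorescence_fit(mcs, ligs, ptot_M, dCp)


def _two_state_bounds(t: np.ndarray) -> FitBounds:
    return FitBounds(lower={"dHu": 1e4, "Tm": float(t[0]) - 5.0},
                     upper={"dHu": 2e6, "Tm": float(t[-1]) + 5.0})


def _global_fluorescence_fit(mcs: MeltCurveSet, ligs, ptot_M,
                             dCp: float = 0.0) -> IsothermalDataset:
    """Shared kN/kU across curves, per-curve (dHu, Tm, bN, bU)."""
    t = mcs.temperature_K
    tref = float(t[0])
    n = mcs.n_wells
    guesses = [initial_guess_two_state(t, mcs.signals[i]) for i in range(n)]
    p0 = [float(np.mean([g["kN"] for g in guesses])),
          float(np.mean([g["kU"] for g in guesses]))]
    for g in guesses:
        p0.extend([g["dHu"], g["Tm"], g["bN"], g["bU"]])
    p0 = np.asarray(p0)
    lo = np.full(p0.size, -np.inf)
    hi = np.full(p0.size, np.inf)
    for i in range(n):
        lo[2 + 4 * i:2 + 4 * i + 2] = (1e4, t[0] - 5.0)
        hi[2 + 4 * i:2 + 4 * i + 2] = (2e6, t[-1] + 5.0)
    p0 = np.clip(p0, lo, hi)

    from scipy.optimize import least_squares

    def residual(p):
        kN, kU = p[0], p[1]
        out = np.empty(n * t.size)
        for i in range(n):
            dHu, tm, bN, bU = p[2 + 4 * i:6 + 4 * i]
            pars = {"dHu": dHu, "Tm": tm, "bN": bN, "kN": kN, "bU": bU, "kU": kU}
            out[i * t.size:(i + 1) * t.size] = (
                signal_two_state(t, pars, tref, dCp) - mcs.signals[i])
        return out

    res = least_squares(residual, p0, bounds=(lo, hi), max_nfev=5000)
    if not res.success:
        warnings.warn("global fluorescence fit did not converge", stacklevel=2)
    dH = res.x[2::4][:n]
    tm = res.x[3::4][:n]
    return IsothermalDataset(ligs, dH, tm, ptot_M,
                             (float(t[0]), float(t[-1])), [], dCp)


def unfolded_fraction_at(ds: IsothermalDataset, ti_K: float) -> TitrationTable:
    """fu(Ti) per concentration from the apparent Ku_obs, sorted by concentration."""
    lo, hi = ds.t_range_K
    if not (lo <= ti_K <= hi):
        raise ValueError(f"Ti = {ti_K:g} K outside fitted range [{lo:g}, {hi:g}] K")
    fu = np.array([fu_two_state(ti_K, dh, tm, ds.dCp)
                   for dh, tm in zip(ds.dH_obs, ds.tm_obs)])
    return TitrationTable(ds.ligand_conc_M.copy(), fu)


# ---------------------------------------------------------------------------
# coupled folding-binding models
# ---------------------------------------------------------------------------

def solve_lfree(Ltot, Ptot: float, Ku: float, Kd: float):
    """Free-ligand concentration for 1:1 binding to the native state.

    Positive root of x^2 + x*(Kd*(Ku+1) + Ptot - Ltot) - Ltot*Kd*(Ku+1) = 0,
    evaluated in a cancellation-safe form; satisfies 0 <= Lfree <= Ltot.
    """
    Ltot = np.asarray(Ltot, dtype=float)
    a = Kd * (Ku + 1.0)
    b = a + Ptot - Ltot
    c = Ltot * a
    disc = np.sqrt(b * b + 4.0 * c)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(b > 0, 2.0 * c / (b + disc), 0.5 * (disc - b))
    x = np.where(c == 0, 0.0, x)
    out = np.clip(x, 0.0, Ltot)
    return out if out.ndim else float(out)


def isothermal_model_1to1(Ltot, Ptot: float, Ku: float, Kd: float):
    """Unfolded fraction fu = Ku/(Ku + 1 + Lfree/Kd) for 1:1 native-state binding."""
    lfree = solve_lfree(Ltot, Ptot, Ku, Kd)
    out = Ku / (Ku + 1.0 + np.asarray(lfree) / Kd)
    return out if np.ndim(out) else float(out)


def solve_lfree_two_site(Ltot, Ptot: float, Ku: float, Kd1: float, Kd2: float):
    """Free ligand for two independent sites on the native state (bisection).

    Mass balance: Ltot = L + F*(L/Kd1*(1+L/Kd2) + L/Kd2*(1+L/Kd1)) with
    F = Ptot/(Ku + (1+L/Kd1)(1+L/Kd2)); the residual is monotone in L, so the
    root is bracketed on [0, Ltot].
    """
    def resid(L, lt):
        q = (1.0 + L / Kd1) * (1.0 + L / Kd2)
        f = Ptot / (Ku + q)
        bound = f * (L / Kd1 * (1.0 + L / Kd2) + L / Kd2 * (1.0 + L / Kd1))
        return L + bound - lt

    scalar = np.ndim(Ltot) == 0
    lt_arr = np.atleast_1d(np.asarray(Ltot, dtype=float))
    out = np.empty_like(lt_arr)
    for i, lt in enumerate(lt_arr):
        if lt == 0:
            out[i] = 0.0
            continue
        out[i] = brentq(resid, 0.0, lt, args=(lt,), xtol=1e-18 * max(lt, 1.0),
                        rtol=1e-15, maxiter=200)
    return float(out[0]) if scalar else out


def isothermal_model_1to2(Ltot, Ptot: float, Ku: float, Kd1: float, Kd2: float):
    """fu = Ku/(Ku + (1+Lfree/Kd1)(1+Lfree/Kd2)); reduces to 1:1 as Kd2 -> inf."""
    lfree = np.asarray(solve_lfree_two_site(Ltot, Ptot, Ku, Kd1, Kd2))
    out = Ku / (Ku + (1.0 + lfree / Kd1) * (1.0 + lfree / Kd2))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# step 2: binding fits
# ---------------------------------------------------------------------------

def pow10(x: float) -> float:
    """10**x without overflow exceptions (saturates to 0/inf)."""
    if math.isnan(x):
        return math.nan
    return float(np.power(10.0, np.clip(x, -308.0, 308.0)))


def _add_linear_kd(fit: ModelFit, log_name: str, out_name: str) -> None:
    est = fit.params[log_name]
    se = fit.std_errors.get(log_name, math.nan)
    fit.derived[out_name] = (pow10(est), pow10(est - fit_engine.Z95 * se),
                             pow10(est + fit_engine.Z95 * se))


def fit_isothermal_kd(table: TitrationTable, ptot_M: float,
                      model: str = "1to1") -> ModelFit:
    """Fit (Ku, Kd) to an unfolded-fraction-vs-concentration table.

    Ku and Kd (and Kd2 for the 1:2 model) are fitted on a log10 scale; the
    linear-scale values appear as derived quantities with asymmetric CIs.
    A fu dynamic range below 0.1 triggers the LOW_AMPLITUDE warning: the
    isothermal temperature should be chosen near the free-protein Tm so the
    unfolded fraction actually responds to the ligand.
    """
    if model not in ("1to1", "1to2"):
        raise ValueError("model must be '1to1' or '1to2'")
    table.require_fit_ready()
    lig = table.ligand_conc_M
    fu = table.response
    low_amplitude = np.ptp(fu) < 0.1
    if low_amplitude:
        warnings.warn("unfolded-fraction dynamic range < 0.1; move Ti closer to "
                      "the free-protein Tm (LOW_AMPLITUDE)", stacklevel=2)

    fu0 = float(np.clip(fu[np.argmin(lig)], 1e-6, 1 - 1e-6))
    ku0 = fu0 / (1.0 - fu0)
    pos = lig[lig > 0]
    kd0 = float(np.median(pos)) if pos.size else 1e-6
    guess = {"log10_Ku": math.log10(max(ku0, 1e-6)),
             "log10_Kd_M": math.log10(kd0)}
    lower = {"log10_Ku": -6.0, "log10_Kd_M": KD_LOG_BOUNDS[0]}
    upper = {"log10_Ku": 6.0, "log10_Kd_M": KD_LOG_BOUNDS[1]}
    if model == "1to2":
        guess["log10_Kd2_M"] = guess["log10_Kd_M"] + 1.0
        lower["log10_Kd2_M"], upper["log10_Kd2_M"] = KD_LOG_BOUNDS
    guess = {k: min(max(v, lower[k]), upper[k]) for k, v in guess.items()}
    bounds = FitBounds(lower=lower, upper=upper)

    def fn(x, p):
        ku = 10.0 ** p["log10_Ku"]
        kd = 10.0 ** p["log10_Kd_M"]
        if model == "1to1":
            return np.asarray(isothermal_model_1to1(x, ptot_M, ku, kd))
        kd2 = 10.0 ** p["log10_Kd2_M"]
        return np.asarray(isothermal_model_1to2(x, ptot_M, ku, kd, kd2))

    fit = nls_fit(fn, lig, fu, guess, bounds,
                  model_name=f"isothermal_{model}")
    if fit.converged:
        fit_engine.apply_quality_filters(fit, bounds,
                                         [k for k in guess if "Kd" in k or "Ku" in k])
        _add_linear_kd(fit, "log10_Kd_M", "Kd_M")
        fit.derived["Ku"] = tuple(
            pow10(v) for v in (fit.params["log10_Ku"], *fit.ci95["log10_Ku"]))
        if model == "1to2":
            _add_linear_kd(fit, "log10_Kd2_M", "Kd2_M")
    if low_amplitude:
        fit.flags.add(FLAG_LOW_AMPLITUDE)
    return fit


# ---------------------------------------------------------------------------
# Tm-shift analysis
# ---------------------------------------------------------------------------

def predict_tm_shift(Ltot, tm0_K: float, dHu: float, kd_M: float) -> np.ndarray:
    """Observed Tm predicted by the melting condition Ku(Tm) = 1 + Ltot/Kd.

    Solves -dHu*(1 - T/Tm0)/(R*T) = ln(1 + Ltot/Kd) for T by root-finding
    (tolerance 1e-9 K); assumes the free ligand equals the total ligand.
    """
    lt = np.atleast_1d(np.asarray(Ltot, dtype=float))
    out = np.empty_like(lt)
    for i, L in enumerate(lt):
        if L <= 0:
            out[i] = tm0_K
            continue
        rhs = math.log1p(L / kd_M)

        def g(T):
            return -dHu * (1.0 - T / tm0_K) / (R * T) - rhs

        hi = tm0_K + 1.0
        while g(hi) < 0:
            hi += 25.0
            if hi > tm0_K + 500:
                raise ValueError("no melting-condition root; check dHu/Kd")
        out[i] = brentq(g, tm0_K, hi, xtol=1e-9)
    return out if np.ndim(Ltot) else float(out[0])


def fit_tm_shift(ligand_conc_M, tm_obs_K, dHu: float, tm0_K: float | None = None,
                 co_fit_tm0: bool = False) -> ModelFit:
    """Estimate Kd from observed melting temperatures versus ligand concentration.

    ``dHu`` (J/mol) is taken from the zero-ligand fit; ``tm0_K`` is either
    fixed (default: the Tm observed at the lowest concentration) or co-fitted.
    All shifts below 0.2 K trigger the NO_SHIFT warning.
    """
    lig = np.asarray(ligand_conc_M, dtype=float)
    tm = np.asarray(tm_obs_K, dtype=float)
    if np.unique(lig).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    order = np.argsort(lig)
    lig, tm = lig[order], tm[order]
    tm0 = float(tm[0]) if tm0_K is None else float(tm0_K)
    no_shift = bool(np.all(np.abs(tm - tm0) < 0.2))
    if no_shift:
        warnings.warn("all Tm shifts < 0.2 K (NO_SHIFT); Kd is not identifiable",
                      stacklevel=2)

    guess = {"log10_Kd_M": math.log10(float(np.median(lig[lig > 0]))
                                      if np.any(lig > 0) else 1e-6)}
    lower = {"log10_Kd_M": KD_LOG_BOUNDS[0]}
    upper = {"log10_Kd_M": KD_LOG_BOUNDS[1]}
    if co_fit_tm0:
        guess["Tm0"] = tm0
        lower["Tm0"] = tm0 - 20.0
        upper["Tm0"] = tm0 + 20.0
    guess["log10_Kd_M"] = min(max(guess["log10_Kd_M"], lower["log10_Kd_M"]),
                              upper["log10_Kd_M"])
    bounds = FitBounds(lower=lower, upper=upper)

    def fn(x, p):
        t0 = p.get("Tm0", tm0)
        return np.asarray(predict_tm_shift(x, t0, dHu, 10.0 ** p["log10_Kd_M"]))

    fit = nls_fit(fn, lig, tm, guess, bounds, model_name="tm_shift")
    if fit.converged:
        fit_engine.apply_quality_filters(fit, bounds, ["log10_Kd_M"])
        _add_linear_kd(fit, "log10_Kd_M", "Kd_M")
        fit.derived["Tm0_K"] = (float(fit.params.get("Tm0", tm0)),) * 3 if not co_fit_tm0 \
            else (fit.params["Tm0"], *fit.ci95["Tm0"])
    if no_shift:
        fit.flags.add(FLAG_NO_SHIFT)
    return fit
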