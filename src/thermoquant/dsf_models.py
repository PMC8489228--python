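"""Melting-curve models and derived protein-stability quantities.

Five models are available for fitting fluorescence (or scattering) melting
curves:

``two_state_eq``
    Reversible two-state unfolding N <-> U.  Gibbs-Helmholtz free energy
    dG(T) = dHu*(1 - T/Tm) + dCp*(T - Tm - T*ln(T/Tm)), equilibrium constant
    Ku = exp(-dG/RT), unfolded fraction fu = Ku/(1+Ku).  Tm is the
    temperature at which half the protein is unfolded; dHu the van 't Hoff
    unfolding enthalpy at Tm; dCp defaults to 0.
``two_state_irrev``
    Kinetically controlled unfolding N -> U with Arrhenius rate
    k(T) = exp[(Ea/R)(1/Tf - 1/T)] per minute (Tf is the temperature where
    k = 1/min) integrated over the temperature ramp at scan rate v (K/min).
``three_state``
    N <-> I <-> U with two Gibbs-Helmholtz equilibria (dH1, Tm1) and
    (dH2, Tm2); the short-lived intermediate contributes an offset-only
    baseline.
``empirical_two_state`` / ``empirical_three_state``
    Logistic stand-ins fu = 1/(1 + exp((Tm - T)/s)) (one or two transitions)
    when a thermodynamic interpretation is not wanted.

All models share sloped linear baselines for the native and unfolded states,
with intercepts referenced to the first temperature of the fitted range.
Derived quantities: Tonset (1% unfolded), dG at 25 C, and condition ranking.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import fit_engine
from .fit_engine import FitBounds, ModelFit, initial_guess_two_state, nls_fit
from .io_formats import MeltCurveSet
from .preprocess import derivative, smooth_spikes

#: gas constant, J mol^-1 K^-1
R = 8.314

T_STANDARD = 298.15  # 25 C, reference temperature for dG

MODEL_NAMES = (
    "two_state_eq", "two_state_irrev", "three_state",
    "empirical_two_state", "empirical_three_state",
)

FU_ONSET = 0.01  # unfolded fraction defining Tonset


# ---------------------------------------------------------------------------
# two-state equilibrium
# ---------------------------------------------------------------------------

def dG_two_state(T, dHu: float, Tm: float, dCp: float = 0.0):
    """Gibbs-Helmholtz free energy of unfolding (J/mol); dG(Tm) = 0 for dCp = 0."""
    T = np.asarray(T, dtype=float)
    dg = dHu * (1.0 - T / Tm)
    if dCp != 0.0:
        dg = dg + dCp * (T - Tm - T * np.log(T / Tm))
    return dg


def ku_two_state(T, dHu: float, Tm: float, dCp: float = 0.0):
    """Equilibrium unfolding constant Ku = exp(-dG/RT)."""
    T = np.asarray(T, dtype=float)
    return np.exp(-dG_two_state(T, dHu, Tm, dCp) / (R * T))


def fu_two_state(T, dHu: float, Tm: float, dCp: float = 0.0):
    """Unfolded fraction Ku/(1+Ku); equals 0.5 at Tm when dCp = 0."""
    # logistic form of Ku/(1+Ku) for overflow safety
    T = np.asarray(T, dtype=float)
    out = expit(-dG_two_state(T, dHu, Tm, dCp) / (R * T))
    return out if out.ndim else float(out)


def dG_at(T, dHu: float, Tm: float, dCp: float = 0.0):
    """Free energy of unfolding at temperature ``T`` (K), in J/mol."""
    return dG_two_state(T, dHu, Tm, dCp)


def baseline_mixture(T, fu, bN, kN, bU, kU, tref):
    """Linear-baseline mixture S = N-line*(1-fu) + U-line*fu."""
    dT = np.asarray(T, dtype=float) - tref
    return (bN + kN * dT) * (1.0 - fu) + (bU + kU * dT) * fu


def signal_two_state(T, params: Mapping[str, float], tref: float, dCp: float = 0.0):
    fu = fu_two_state(T, params["dHu"], params["Tm"], dCp)
    return baseline_mixture(T, fu, params["bN"], params["kN"],
                            params["bU"], params["kU"], tref)


# ---------------------------------------------------------------------------
# two-state irreversible
# ---------------------------------------------------------------------------

def rate_irreversible(T, Ea: float, Tf: float):
    """Arrhenius unfolding rate in min^-1; equals 1/min at T = Tf by construction."""
    T = np.asarray(T, dtype=float)
    return np.exp((Ea / R) * (1.0 / Tf - 1.0 / T))


def fu_irreversible(T_grid, Ea: float, Tf: float, scan_rate: float = 1.0,
                    refine: int = 30):
    """Unfolded fraction for first-order irreversible unfolding during a ramp.

    fu(T) = 1 - exp[-(1/v) * int_{T0}^{T} k(T') dT'], evaluated by trapezoid
    on a ``refine``-times finer grid and interpolated back; fu(T0) = 0.
    """
    t = np.asarray(T_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be ascending")
    fine = np.linspace(t[0], t[-1], refine * (t.size - 1) + 1)
    k = rate_irreversible(fine, Ea, Tf)
    integral = np.concatenate([[0.0], np.cumsum(
        0.5 * (k[1:] + k[:-1]) * np.diff(fine))])
    fu_fine = 1.0 - np.exp(-integral / scan_rate)
    return np.interp(t, fine, fu_fine)


def signal_irreversible(T_grid, params: Mapping[str, float], tref: float,
                        scan_rate: float = 1.0):
    fu = fu_irreversible(T_grid, params["Ea"], params["Tf"], scan_rate)
    return baseline_mixture(T_grid, fu, params["bN"], params["kN"],
                            params["bU"], params["kU"], tref)


# ---------------------------------------------------------------------------
# three-state equilibrium
# ---------------------------------------------------------------------------

def fractions_three_state(T, dH1: float, Tm1: float, dH2: float, Tm2: float,
                          dCp: float = 0.0):
    """Population fractions (fN, fI, fU) of the N <-> I <-> U scheme.

    K1 and K2 are Gibbs-Helmholtz constants with (dH1, Tm1) and (dH2, Tm2);
    fN = 1/(1 + K1 + K1*K2), fI = K1*fN, fU = K1*K2*fN; the fractions sum
    to 1 by construction.
    """
    K1 = ku_two_state(T, dH1, Tm1, dCp)
    K2 = ku_two_state(T, dH2, Tm2, dCp)
    fN = 1.0 / (1.0 + K1 + K1 * K2)
    return fN, K1 * fN, K1 * K2 * fN


def signal_three_state(T, params: Mapping[str, float], tref: float,
                       dCp: float = 0.0):
    fN, fI, fU = fractions_three_state(T, params["dH1"], params["Tm1"],
                                       params["dH2"], params["Tm2"], dCp)
    dT = np.asarray(T, dtype=float) - tref
    return ((params["bN"] + params["kN"] * dT) * fN
            + params["bI"] * fI
            + (params["bU"] + params["kU"] * dT) * fU)


# ---------------------------------------------------------------------------
# empirical (logistic) models
# ---------------------------------------------------------------------------

def fu_empirical(T, Tm: float, s: float):
    """Logistic unfolded fraction 1/(1+exp((Tm-T)/s)); s > 0 sets the steepness."""
    if s <= 0:
        raise ValueError("steepness s must be > 0")
    T = np.asarray(T, dtype=float)
    out = expit((T - Tm) / s)
    return out if out.ndim else float(out)


def signal_empirical_two_state(T, params: Mapping[str, float], tref: float):
    fu = fu_empirical(T, params["Tm"], params["s"])
    return baseline_mixture(T, fu, params["bN"], params["kN"],
                            params["bU"], params["kU"], tref)


def signal_empirical_three_state(T, params: Mapping[str, float], tref: float):
    f1 = fu_empirical(T, params["Tm1"], params["s1"])
    f2 = fu_empirical(T, params["Tm2"], params["s2"])
    fN, fI, fU = (1.0 - f1), f1 * (1.0 - f2), f1 * f2
    dT = np.asarray(T, dtype=float) - tref
    return ((params["bN"] + params["kN"] * dT) * fN
            + params["bI"] * fI
            + (params["bU"] + params["kU"] * dT) * fU)


# ---------------------------------------------------------------------------
# derived stability quantities
# ---------------------------------------------------------------------------

def tonset_closed_form(dHu: float, Tm: float) -> float:
    """Tonset for dCp = 0: dHu*Tm / (dHu + R*Tm*ln 99)."""
    return dHu * Tm / (dHu + R * Tm * math.log(99.0))


def tonset(params: Mapping[str, float], model: str = "two_state_eq",
           dCp: float = 0.0) -> float:
    """Temperature at which 1% of the molecules are unfolded.

    Found by root-finding on the model's unfolded-fraction curve to a
    tolerance of 1e-9 K.  Supported for the equilibrium and empirical
    two-state models.
    """
    if model == "two_state_eq":
        def fu(T):
            return float(fu_two_state(T, params["dHu"], params["Tm"], dCp))
        tm = params["Tm"]
    elif model == "empirical_two_state":
        def fu(T):
            return float(fu_empirical(T, params["Tm"], params["s"]))
        tm = params["Tm"]
    else:
        raise ValueError(f"tonset not defined for model {model!r}")
    lo = tm - 10.0
    while fu(lo) > FU_ONSET:
        lo -= 25.0
        if lo < 1.0:
            raise ValueError("no Tonset root above 0 K for these parameters")
    return brentq(lambda T: fu(T) - FU_ONSET, lo, tm, xtol=1e-9)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _two_transition_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Locate two transition midpoints from the derivative (dominant first)."""
    dy = derivative(smooth_spikes(y, 3), t)
    mag = np.abs(dy[1:-1])
    ti = t[1:-1]
    i1 = int(np.argmax(mag))
    away = np.abs(ti - ti[i1]) > 5.0
    if away.any():
        i2 = int(np.flatnonzero(away)[np.argmax(mag[away])])
    else:
        i2 = min(i1 + 1, mag.size - 1)
    tm_a, tm_b = sorted((float(ti[i1]), float(ti[i2])))
    mid_idx = int(np.argmin(np.abs(t - 0.5 * (tm_a + tm_b))))
    return tm_a, tm_b, float(y[mid_idx])


def _model_setup(model_name: str, t: np.ndarray, y: np.ndarray,
                 dCp: float, scan_rate: float):
    """Return (signal_fn, initial guess, bounds, thermodynamic-parameter names)."""
    tref = float(t[0])
    t_lo, t_hi = float(t[0]), float(t[-1])
    tm_bounds = (t_lo - 5.0, t_hi + 5.0)
    dh_bounds = (1.0e4, 2.0e6)  # 10 to 2000 kJ/mol

    if model_name == "two_state_eq":
        guess = initial_guess_two_state(t, y)
        bounds = FitBounds(lower={"dHu": dh_bounds[0], "Tm": tm_bounds[0]},
                           upper={"dHu": dh_bounds[1], "Tm": tm_bounds[1]})
        return (lambda x, p: signal_two_state(x, p, tref, dCp),
                guess, bounds, ("dHu", "Tm"))

    if model_name == "empirical_two_state":
        g = initial_guess_two_state(t, y)
        guess = {"Tm": g["Tm"], "s": 2.0, "bN": g["bN"], "kN": g["kN"],
                 "bU": g["bU"], "kU": g["kU"]}
        bounds = FitBounds(lower={"Tm": tm_bounds[0], "s": 0.05},
                           upper={"Tm": tm_bounds[1], "s": 50.0})
        return (lambda x, p: signal_empirical_two_state(x, p, tref),
                guess, bounds, ("Tm", "s"))

    if model_name == "two_state_irrev":
        g = initial_guess_two_state(t, y)
        guess = {"Ea": 3.0e5, "Tf": g["Tm"], "bN": g["bN"], "kN": g["kN"],
                 "bU": g["bU"], "kU": g["kU"]}
        bounds = FitBounds(lower={"Ea": dh_bounds[0], "Tf": tm_bounds[0]},
                           upper={"Ea": dh_bounds[1], "Tf": t_hi + 50.0})
        return (lambda x, p: signal_irreversible(x, p, tref, scan_rate),
                guess, bounds, ("Ea", "Tf"))

    if model_name == "three_state":
        tm1, tm2, b_mid = _two_transition_guess(t, y)
        g = initial_guess_two_state(t, y)
        guess = {"dH1": 3.0e5, "Tm1": tm1, "dH2": 3.0e5, "Tm2": tm2,
                 "bN": g["bN"], "kN": g["kN"], "bI": b_mid,
                 "bU": g["bU"], "kU": g["kU"]}
        bounds = FitBounds(
            lower={"dH1": dh_bounds[0], "dH2": dh_bounds[0],
                   "Tm1": tm_bounds[0], "Tm2": tm_bounds[0]},
            upper={"dH1": dh_bounds[1], "dH2": dh_bounds[1],
                   "Tm1": tm_bounds[1], "Tm2": tm_bounds[1]})
        return (lambda x, p: signal_three_state(x, p, tref, dCp),
                guess, bounds, ("dH1", "Tm1", "dH2", "Tm2"))

    if model_name == "empirical_three_state":
        tm1, tm2, b_mid = _two_transition_guess(t, y)
        g = initial_guess_two_state(t, y)
        guess = {"Tm1": tm1, "s1": 2.0, "Tm2": tm2, "s2": 2.0,
                 "bN": g["bN"], "kN": g["kN"], "bI": b_mid,
                 "bU": g["bU"], "kU": g["kU"]}
        bounds = FitBounds(
            lower={"Tm1": tm_bounds[0], "Tm2": tm_bounds[0], "s1": 0.05, "s2": 0.05},
            upper={"Tm1": tm_bounds[1], "Tm2": tm_bounds[1], "s1": 50.0, "s2": 50.0})
        return (lambda x, p: signal_empirical_three_state(x, p, tref),
                guess, bounds, ("Tm1", "s1", "Tm2", "s2"))

    raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")


def fit_melt_curve(mcs: MeltCurveSet, well: str, model_name: str = "two_state_eq",
                   dCp: float = 0.0, scan_rate: float = 1.0,
                   rel_err_max_pct: float = 50.0,
                   boundary_tol_frac: float = 0.01) -> ModelFit:
    """Fit one well's (preprocessed) melting trace with the chosen model.

    Returns a ModelFit carrying quality flags; a flat trace yields
    CONSTANT_SIGNAL without fitting.
    """
    t = mcs.temperature_K
    y = mcs.trace(well)
    if np.ptp(y) == 0:
        return nls_fit(lambda x, p: np.zeros_like(x), t, y, {"Tm": float(t[0])},
                       model_name=model_name)
    fn, guess, bounds, thermo = _model_setup(model_name, t, y, dCp, scan_rate)
    bounds.boundary_tol_frac = boundary_tol_frac
    guess = {k: min(max(v, bounds.lo(k)), bounds.hi(k)) for k, v in guess.items()}
    fit = nls_fit(fn, t, y, guess, bounds, model_name=model_name)
    if fit.converged:
        fit_engine.apply_quality_filters(fit, bounds, thermo, rel_err_max_pct)
    return fit


def derived_stability(fit: ModelFit, dCp: float = 0.0) -> dict[str, float]:
    """Tonset and (for the equilibrium model) dG at 25 C from a fitted curve."""
    out: dict[str, float] = {}
    if fit.model in ("two_state_eq", "empirical_two_state"):
        out["Tonset_K"] = tonset(fit.params, fit.model, dCp)
    if fit.model == "two_state_eq":
        out["dG25_J_mol"] = float(dG_at(T_STANDARD, fit.params["dHu"],
                                        fit.params["Tm"], dCp))
    return out


def rank_conditions(fits, criterion: str = "Tm", dCp: float = 0.0) -> pd.DataFrame:
    """Rank fitted conditions by Tm, Tonset or dG25 (descending = most stable).

    ``fits`` is an iterable of ``(fit_id, ModelFit)``.  Flagged fits are not
    ranked; they appear at the bottom with ``section == "flagged"``.  Ties are
    broken by fit id.  A criterion a model cannot provide (e.g. dG25 for an
    empirical fit) raises ValueError.
    """
    if criterion not in ("Tm", "Tonset", "dG25"):
        raise ValueError("criterion must be one of Tm, Tonset, dG25")
    rows = []
    for fit_id, fit in fits:
        if criterion == "Tm":
            if "Tm" not in fit.params:
                raise ValueError(f"fit {fit_id!r} ({fit.model}) has no Tm parameter")
            value = fit.params["Tm"]
        elif criterion == "Tonset":
            value = tonset(fit.params, fit.model, dCp)
        else:  # dG25
            if fit.model != "two_state_eq":
                raise ValueError(
                    f"dG25 is only defined for the equilibrium two-state model "
                    f"(fit {fit_id!r} used {fit.model})")
            value = float(dG_at(T_STANDARD, fit.params["dHu"], fit.params["Tm"], dCp))
        rows.append({"fit_id": str(fit_id), criterion: value,
                     "flagged": bool(fit.flags),
                     "flags": ";".join(sorted(fit.flags))})
    frame = pd.DataFrame(rows)
    ranked = frame[~frame["flagged"]].sort_values(
        [criterion, "fit_id"], ascending=[False, True], kind="stable")
    flagged = frame[frame["flagged"]].sort_values("fit_id", kind="stable")
    ranked = ranked.assign(section="ranked")
    flagged = flagged.assign(section="flagged")
    out = pd.concat([ranked, flagged], ignore_index=True)
    out.insert(0, "rank", [i + 1 for i in range(len(ranked))] + [math.nan] * len(flagged))
    return out
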