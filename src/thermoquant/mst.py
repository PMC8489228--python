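"""MST binding analysis: Fnorm, initial-fluorescence QC and binding fits.

Fnorm is the quotient of the mean fluorescence in a "hot" window (after IR
laser activation, t >= 0) over a "cold" window (before activation, t <= 0);
analysing the first 1-2 s after the temperature jump keeps thermally induced
artefacts small.  Before fitting, the cold-window (initial) fluorescence of
every capillary should be checked: it must stay within +/-20% of the
across-capillary average, otherwise the ligand itself changes the fluorescence
and the binding signal is suspect.

Binding models express the response (Fnorm, or raw fluorescence for
quenching/enhancement titrations) as a linear combination of the signals of
the unbound and complexed protein:

    response = RF1 * (1 - fb) + RF2 * fb

with the bound fraction fb from the exact 1:1 mass-balance quadratic (no
free-ligand approximation) or from a two-site independent-site model with
identical or different site constants.  Kd is fitted on a log10 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import fit_engine
from .fit_engine import FLAG_LOW_AMPLITUDE, FitBounds, ModelFit, nls_fit
from .io_formats import MstTraceSet, TitrationTable

MST_MODELS = ("1to1", "two_site_identical", "two_site_different")

QC_MAX_DEVIATION = 0.20  # +/-20% of the average initial fluorescence


@dataclass
class MstWindows:
    """Cold and hot time windows (seconds) for Fnorm.

    The cold window must lie entirely at t <= 0 (pre-IR), the hot window at
    t >= 0.  Defaults follow common practice: cold [-1, 0] s, hot [0, 2] s.
    """

    cold: tuple[float, float] = (-1.0, 0.0)
    hot: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self):
        if not (self.cold[0] < self.cold[1] <= 0):
            raise ValueError("cold window must be increasing and entirely <= 0 s")
        if not (0 <= self.hot[0] < self.hot[1]):
            raise ValueError("hot window must be increasing and entirely >= 0 s")

    def masks(self, time_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # t = 0 is IR switch-on: it belongs to the hot (post-laser) side only
        cold = (time_s >= self.cold[0]) & (time_s <= self.cold[1]) & (time_s < 0)
        hot = (time_s >= self.hot[0]) & (time_s <= self.hot[1]) & (time_s >= 0)
        for name, mask in (("cold", cold), ("hot", hot)):
            if mask.sum() < 2:
                raise ValueError(f"{name} window contains {int(mask.sum())} samples (< 2)")
        return cold, hot


@dataclass
class QcReport:
    """Initial-fluorescence check: per-capillary cold means vs the global mean."""

    frame: pd.DataFrame
    global_mean: float
    max_deviation: float = QC_MAX_DEVIATION

    @property
    def all_passed(self) -> bool:
        return bool(self.frame["passed"].all())

    def failing(self) -> list[str]:
        return list(self.frame.loc[~self.frame["passed"], "capillary_id"])


def compute_fnorm(traces: MstTraceSet, windows: MstWindows | None = None) -> TitrationTable:
    """Fnorm = mean(hot window) / mean(cold window) per capillary.

    Returns a (ligand concentration, Fnorm) titration table.  Fnorm is a raw
    ratio (multiply by 1000 for the per-mille convention); it is invariant
    under uniform scaling of a trace.
    """
    windows = windows or MstWindows()
    cold, hot = windows.masks(traces.time_s)
    f_cold = traces.fluorescence[:, cold].mean(axis=1)
    if np.any(f_cold == 0):
        raise ValueError("zero cold-window mean fluorescence")
    fnorm = traces.fluorescence[:, hot].mean(axis=1) / f_cold
    return TitrationTable(traces.ligand_conc_M.copy(), fnorm)


def initial_fluorescence_check(traces: MstTraceSet,
                               windows: MstWindows | None = None,
                               max_deviation: float = QC_MAX_DEVIATION) -> QcReport:
    """Flag capillaries whose initial (cold-window) fluorescence is an outlier.

    A capillary fails iff its cold mean deviates from the across-capillary
    average by more than ``max_deviation`` (default 20%).
    """
    windows = windows or MstWindows()
    cold, _ = windows.masks(traces.time_s)
    means = traces.fluorescence[:, cold].mean(axis=1)
    global_mean = float(means.mean())
    deviation = means / global_mean - 1.0
    frame = pd.DataFrame({
        "capillary_id": traces.capillary_ids,
        "ligand_conc_M": traces.ligand_conc_M,
        "cold_mean": means,
        "deviation_frac": deviation,
        "passed": np.abs(deviation) <= max_deviation,
    })
    return QcReport(frame, global_mean, max_deviation)


# ---------------------------------------------------------------------------
# binding models
# ---------------------------------------------------------------------------

def fraction_bound_1to1(Ltot, Ptot: float, Kd: float):
    """Bound-protein fraction from the exact 1:1 mass balance.

    fb = (Ptot + Ltot + Kd - sqrt((Ptot+Ltot+Kd)^2 - 4*Ptot*Ltot)) / (2*Ptot),
    evaluated in the cancellation-safe form fb = 2*Ltot/(S + sqrt(S^2 - 4PL));
    handles ligand depletion exactly.
    """
    Ltot = np.asarray(Ltot, dtype=float)
    s = Ptot + Ltot + Kd
    disc = np.sqrt(s * s - 4.0 * Ptot * Ltot)
    out = 2.0 * Ltot / (s + disc)
    return out if out.ndim else float(out)


def _free_ligand_two_site(Ltot, Ptot: float, Kd1: float, Kd2: float) -> np.ndarray:
    """Free ligand with two independent sites per protein (bisection)."""
    def resid(L, lt):
        theta = L / (Kd1 + L) + L / (Kd2 + L)
        return L + Ptot * theta - lt

    lt_arr = np.atleast_1d(np.asarray(Ltot, dtype=float))
    out = np.empty_like(lt_arr)
    for i, lt in enumerate(lt_arr):
        out[i] = 0.0 if lt == 0 else brentq(resid, 0.0, lt, args=(lt,),
                                            xtol=1e-18 * max(lt, 1.0), rtol=1e-15)
    return out


def fraction_bound_two_site(Ltot, Ptot: float, Kd1: float, Kd2: float):
    """Average site occupancy (theta1 + theta2)/2 for two independent sites."""
    lfree = _free_ligand_two_site(Ltot, Ptot, Kd1, Kd2)
    out = 0.5 * (lfree / (Kd1 + lfree) + lfree / (Kd2 + lfree))
    return out if np.ndim(Ltot) else float(out[0])


@dataclass
class MstFitParams:
    kd_M: float
    rf1: float
    rf2: float
    kd2_M: float | None = None

    def __post_init__(self):
        if self.kd_M <= 0 or (self.kd2_M is not None and self.kd2_M <= 0):
            raise ValueError("Kd must be > 0")


def response_model(Ltot, Ptot: float, params: MstFitParams, model: str = "1to1"):
    """response = RF1*(1-fb) + RF2*fb for the chosen occupancy model.

    RF1 and RF2 are the response levels of fully unbound and fully complexed
    protein; at Ltot = 0 the response equals RF1 and at saturation RF2.
    """
    if model not in MST_MODELS:
        raise ValueError(f"model must be one of {MST_MODELS}")
    if model == "1to1":
        fb = fraction_bound_1to1(Ltot, Ptot, params.kd_M)
    elif model == "two_site_identical":
        fb = fraction_bound_two_site(Ltot, Ptot, params.kd_M, params.kd_M)
    else:
        kd2 = params.kd2_M if params.kd2_M is not None else params.kd_M
        fb = fraction_bound_two_site(Ltot, Ptot, params.kd_M, kd2)
    return params.rf1 * (1.0 - np.asarray(fb)) + params.rf2 * np.asarray(fb)


def fit_mst_kd(table: TitrationTable, ptot_M: float, model: str = "1to1") -> ModelFit:
    """Least-squares fit of (Kd, RF1, RF2) to a response titration.

    Kd is fitted on a log10 scale (reported linearly as a derived quantity
    with an asymmetric CI).  Works identically for Fnorm and for raw
    fluorescence quenching/enhancement titrations.  A fitted amplitude below
    three times the residual noise triggers the LOW_AMPLITUDE warning.
    """
    if model not in MST_MODELS:
        raise ValueError(f"model must be one of {MST_MODELS}")
    table.require_fit_ready()
    lig = table.ligand_conc_M
    y = table.response

    idx = np.argsort(lig)
    lo_resp = float(np.mean(y[idx[:2]]))
    hi_resp = float(np.mean(y[idx[-2:]]))
    pos = lig[lig > 0]
    kd0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1e-6
    guess = {"log10_Kd_M": math.log10(kd0), "RF1": lo_resp, "RF2": hi_resp}
    lower = {"log10_Kd_M": -12.0}
    upper = {"log10_Kd_M": -1.0}
    if model == "two_site_different":
        guess["log10_Kd2_M"] = guess["log10_Kd_M"] + 1.0
        lower["log10_Kd2_M"], upper["log10_Kd2_M"] = -12.0, -1.0
    guess["log10_Kd_M"] = min(max(guess["log10_Kd_M"], -12.0), -1.0)
    bounds = FitBounds(lower=lower, upper=upper)

    def fn(x, p):
        pars = MstFitParams(10.0 ** p["log10_Kd_M"], p["RF1"], p["RF2"],
                            10.0 ** p["log10_Kd2_M"] if "log10_Kd2_M" in p else None)
        return np.asarray(response_model(x, ptot_M, pars, model))

    fit = nls_fit(fn, lig, y, guess, bounds, model_name=f"mst_{model}")
    if fit.converged:
        kd_names = [k for k in guess if k.startswith("log10_Kd")]
        fit_engine.apply_quality_filters(fit, bounds, kd_names)
        from .isothermal import _add_linear_kd
        _add_linear_kd(fit, "log10_Kd_M", "Kd_M")
        if "log10_Kd2_M" in fit.params:
            _add_linear_kd(fit, "log10_Kd2_M", "Kd2_M")
        # amplitude actually spanned over the measured concentrations (RF1 is
        # unconstrained when the curve saturates below the lowest point)
        amplitude = float(np.ptp(fn(lig, fit.params)))
        if amplitude < 3.0 * fit.residual_rms:
            warnings.warn("binding amplitude below 3x residual noise "
                          "(LOW_AMPLITUDE)", stacklevel=2)
            fit.flags.add(FLAG_LOW_AMPLITUDE)
    return fit
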