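"""Seeded generators for DSF plates, ligand-series melts and MST trace sets.

Every generator is a pure function of (scenario, seed): the same scenario
always produces byte-identical data, and the ground truth is carried in the
scenario so recovery tests can compare estimates against it.

The defaults emulate the experimental designs the package targets:

* melt grids 20-90 C at 1 C/min with sloped linear baselines and Gaussian
  noise expressed as a fraction of the unfolding amplitude;
* a ligand titration of 16 concentrations (1.5-fold dilution from 150 uM)
  against 15 uM protein, with melting curves generated from the coupled
  folding-binding equilibrium (temperature-dependent Ku, 1:1 native-state
  binding), so the apparent Tm rises with ligand concentration;
* MST traces with a cold plateau, a T-jump drop whose amplitude interpolates
  linearly between the unbound and bound levels with the bound fraction, and
  a single-exponential decay (enough to exercise window logic; not a
  physical thermophoresis model) — 16 capillaries, 2-fold dilution from
  150 uM, 25 nM labelled protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .dsf_models import (ku_two_state, signal_empirical_three_state,
                         signal_two_state)
from .io_formats import MeltCurveSet, MstTraceSet, _empty_annotations
from .isothermal import solve_lfree

DEFAULT_BASELINES = {"bN": 0.8, "kN": -0.0010, "bU": 1.2, "kU": -0.0025}


def dilution_series(top_M: float, factor: float, n: int) -> np.ndarray:
    """Serial dilution: n concentrations from ``top_M`` downward by ``factor``."""
    return top_M / factor ** np.arange(n)


# ---------------------------------------------------------------------------
# DSF plates
# ---------------------------------------------------------------------------

@dataclass
class DsfScenario:
    """Ground truth for a synthetic melt plate.

    ``wells`` maps well id -> (model name, parameter dict); ``grid`` is
    (start, stop, step) in Kelvin; ``noise_sd`` is the Gaussian noise sigma
    as a fraction of each well's signal amplitude.
    """

    wells: dict[str, tuple[str, dict[str, float]]]
    grid: tuple[float, float, float] = (293.15, 363.15, 1.0)
    noise_sd: float = 0.005
    seed: int = 0
    conditions: dict[str, str] = dc_field(default_factory=dict)
    ligand_conc_M: dict[str, float] = dc_field(default_factory=dict)

    def temperatures(self) -> np.ndarray:
        start, stop, step = self.grid
        return np.arange(start, stop + 0.5 * step, step)


def _well_signal(t: np.ndarray, model: str, params: dict[str, float]) -> np.ndarray:
    tref = float(t[0])
    if model == "two_state_eq":
        return signal_two_state(t, params, tref, params.get("dCp", 0.0))
    if model == "empirical_three_state":
        return signal_empirical_three_state(t, params, tref)
    raise ValueError(f"generator does not support model {model!r}")


def gen_dsf_plate(scenario: DsfScenario) -> MeltCurveSet:
    """Generate a melt plate: model signal plus Gaussian noise per well."""
    t = scenario.temperatures()
    rng = np.random.default_rng(scenario.seed)
    well_ids = list(scenario.wells)
    signals = np.empty((len(well_ids), t.size))
    for i, well in enumerate(well_ids):
        model, params = scenario.wells[well]
        clean = _well_signal(t, model, params)
        amplitude = np.ptp(clean)
        signals[i] = clean + rng.normal(0.0, scenario.noise_sd * amplitude, t.size)
    ann = _empty_annotations(well_ids)
    for well in well_ids:
        if well in scenario.conditions:
            ann.loc[well, "condition"] = scenario.conditions[well]
        if well in scenario.ligand_conc_M:
            ann.loc[well, "ligand_conc_M"] = scenario.ligand_conc_M[well]
    return MeltCurveSet(t, signals, well_ids, ann, "dye")


def two_state_plate_scenario(n_wells: int = 96, tm_range: tuple[float, float] = (318.0, 338.0),
                             dHu: float = 4.0e5, noise_sd: float = 0.005,
                             seed: int = 0) -> DsfScenario:
    """A screening plate of two-state melters with Tm spread over ``tm_range``."""
    tms = np.linspace(tm_range[0], tm_range[1], n_wells)
    wells = {}
    for i, tm in enumerate(tms):
        well = f"{chr(ord('A') + i // 12)}{i % 12 + 1}"
        wells[well] = ("two_state_eq", {"dHu": dHu, "Tm": float(tm),
                                        **DEFAULT_BASELINES})
    return DsfScenario(wells=wells, noise_sd=noise_sd, seed=seed)


def ph_screen_scenario(n_conditions: int = 10, tm_low: float = 318.15,
                       tm_high: float = 330.15, dHu: float = 4.0e5,
                       noise_sd: float = 0.005, seed: int = 0) -> DsfScenario:
    """A pH-screen-like plate: Tm increases monotonically with condition index."""
    tms = np.linspace(tm_low, tm_high, n_conditions)
    wells, conditions = {}, {}
    for i, tm in enumerate(tms):
        well = f"E{i + 1}"
        wells[well] = ("two_state_eq", {"dHu": dHu, "Tm": float(tm),
                                        **DEFAULT_BASELINES})
        conditions[well] = f"pH_{5.0 + 0.5 * i:.1f}"
    return DsfScenario(wells=wells, conditions=conditions,
                       noise_sd=noise_sd, seed=seed)


def two_transition_scenario(tm1: float = 318.15, tm2: float = 348.15,
                            s1: float = 1.5, s2: float = 2.5,
                            minor_amplitude: float = 0.25,
                            noise_sd: float = 0.005, seed: int = 0) -> DsfScenario:
    """One well with a dominant low-T transition plus a minor high-T one."""
    b = DEFAULT_BASELINES
    b_mid = b["bN"] + (1.0 - minor_amplitude) * (b["bU"] - b["bN"])
    params = {"Tm1": tm1, "s1": s1, "Tm2": tm2, "s2": s2,
              "bN": b["bN"], "kN": b["kN"], "bI": b_mid,
              "bU": b["bU"], "kU": b["kU"]}
    return DsfScenario(wells={"A1": ("empirical_three_state", params)},
                       noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# coupled folding-binding ligand series
# ---------------------------------------------------------------------------

@dataclass
class LigandSeriesScenario:
    """Ground truth for a DSF ligand titration with 1:1 native-state binding.

    Defaults mirror a 16-point, 1.5-fold dilution from 150 uM against 15 uM
    protein, with the free protein melting at 42 C (dHu 400 kJ/mol) and a
    2 uM dissociation constant.
    """

    kd_M: float = 2.0e-6
    ptot_M: float = 15.0e-6
    tm0_K: float = 315.15
    dHu: float = 4.0e5
    top_M: float = 150.0e-6
    dilution_factor: float = 1.5
    n_concentrations: int = 16
    include_zero: bool = False
    grid: tuple[float, float, float] = (293.15, 338.15, 0.5)
    noise_sd: float = 0.005
    baselines: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_BASELINES))
    seed: int = 0

    def concentrations(self) -> np.ndarray:
        conc = dilution_series(self.top_M, self.dilution_factor,
                               self.n_concentrations)
        if self.include_zero:
            conc = np.append(conc, 0.0)
        return conc


def coupled_fu(t: np.ndarray, ltot_M: float, sc: LigandSeriesScenario) -> np.ndarray:
    """Unfolded fraction versus temperature under the coupled equilibrium.

    Ku(T) from Gibbs-Helmholtz (dCp = 0); at every temperature the free
    ligand is solved from the 1:1 mass balance, then
    fu = Ku/(Ku + 1 + Lfree/Kd).
    """
    ku = np.asarray(ku_two_state(t, sc.dHu, sc.tm0_K))
    fu = np.empty_like(ku)
    for j, k in enumerate(ku):
        lfree = solve_lfree(ltot_M, sc.ptot_M, float(k), sc.kd_M)
        fu[j] = k / (k + 1.0 + lfree / sc.kd_M)
    return fu


def gen_ligand_series(scenario: LigandSeriesScenario) -> MeltCurveSet:
    """Generate the melt-curve series of a stabilizing-ligand titration."""
    start, stop, step = scenario.grid
    t = np.arange(start, stop + 0.5 * step, step)
    rng = np.random.default_rng(scenario.seed)
    conc = scenario.concentrations()
    b = scenario.baselines
    tref = float(t[0])
    well_ids, rows, ligs = [], [], {}
    for i, L in enumerate(conc):
        fu = coupled_fu(t, float(L), scenario)
        clean = ((b["bN"] + b["kN"] * (t - tref)) * (1 - fu)
                 + (b["bU"] + b["kU"] * (t - tref)) * fu)
        amplitude = np.ptp(clean)
        well = f"C{i + 1}"
        well_ids.append(well)
        ligs[well] = float(L)
        rows.append(clean + rng.normal(0.0, scenario.noise_sd * amplitude, t.size))
    ann = _empty_annotations(well_ids)
    for well, L in ligs.items():
        ann.loc[well, "ligand_conc_M"] = L
        ann.loc[well, "condition"] = "titration"
    return MeltCurveSet(t, np.vstack(rows), well_ids, ann, "dye")


def apparent_tm(t: np.ndarray, ltot_M: float, sc: LigandSeriesScenario) -> float:
    """Temperature where the coupled-model unfolded fraction crosses 0.5."""
    fu = coupled_fu(t, ltot_M, sc)
    return float(np.interp(0.5, fu, t))


# ---------------------------------------------------------------------------
# MST traces
# ---------------------------------------------------------------------------

@dataclass
class MstScenario:
    """Ground truth for a synthetic MST trace set.

    Traces are F0 for t < 0, then F0*[1 - A(fb)*(1 - exp(-t/tau))] for
    t >= 0, with the T-jump amplitude A interpolating linearly between
    ``amp_unbound`` and ``amp_bound`` with the 1:1 bound fraction.
    ``gain_jitter`` adds capillary-to-capillary multiplicative gain spread
    (fraction of F0) to exercise the initial-fluorescence QC.
    """

    kd_M: float = 1.0e-6
    ptot_M: float = 25.0e-9
    top_M: float = 150.0e-6
    dilution_factor: float = 2.0
    n_capillaries: int = 16
    f0: float = 1000.0
    amp_unbound: float = 0.10
    amp_bound: float = 0.22
    tau_s: float = 1.2
    t_start_s: float = -5.0
    t_end_s: float = 25.0
    n_times: int = 200
    noise_sd: float = 0.005
    gain_jitter: float = 0.0
    seed: int = 0

    def concentrations(self) -> np.ndarray:
        return dilution_series(self.top_M, self.dilution_factor, self.n_capillaries)

    def times(self) -> np.ndarray:
        return np.linspace(self.t_start_s, self.t_end_s, self.n_times)


def mst_amplitude(fb, sc: MstScenario):
    """T-jump amplitude as a linear interpolation between unbound and bound."""
    return sc.amp_unbound + (sc.amp_bound - sc.amp_unbound) * np.asarray(fb)


def gen_mst_traces(scenario: MstScenario) -> MstTraceSet:
    """Generate MST traces with known per-capillary bound fractions."""
    from .mst import fraction_bound_1to1

    t = scenario.times()
    conc = scenario.concentrations()
    rng = np.random.default_rng(scenario.seed)
    fb = np.asarray(fraction_bound_1to1(conc, scenario.ptot_M, scenario.kd_M))
    amps = mst_amplitude(fb, scenario)
    traces = np.empty((conc.size, t.size))
    for i, a in enumerate(amps):
        gain = 1.0 + (scenario.gain_jitter * rng.standard_normal()
                      if scenario.gain_jitter else 0.0)
        f0 = scenario.f0 * gain
        clean = np.where(t < 0, f0,
                         f0 * (1.0 - a * (1.0 - np.exp(-np.clip(t, 0, None)
                                                       / scenario.tau_s))))
        traces[i] = clean + rng.normal(0.0, scenario.noise_sd * f0, t.size)
    ids = [f"C{i + 1}" for i in range(conc.size)]
    return MstTraceSet(t, traces, ids, conc, scenario.ptot_M)


def mst_truth_fnorm(scenario: MstScenario, hot_times: np.ndarray, fb) -> np.ndarray:
    """Noiseless Fnorm over a hot window: 1 - A(fb)*(1 - mean exp(-t/tau))."""
    decay = np.mean(np.exp(-np.clip(hot_times, 0, None) / scenario.tau_s))
    return 1.0 - mst_amplitude(fb, scenario) * (1.0 - decay)


def truth_table(scenario) -> pd.DataFrame:
    """Ground-truth parameters of a scenario as a tidy table (for truth.csv)."""
    rows = []
    if isinstance(scenario, DsfScenario):
        for well, (model, params) in scenario.wells.items():
            for name, value in params.items():
                rows.append({"id": well, "model": model,
                             "parameter": name, "value": value})
    elif isinstance(scenario, LigandSeriesScenario):
        for name in ("kd_M", "ptot_M", "tm0_K", "dHu", "top_M",
                     "dilution_factor", "n_concentrations", "noise_sd"):
            rows.append({"id": "series", "model": "coupled_1to1",
                         "parameter": name, "value": getattr(scenario, name)})
    elif isinstance(scenario, MstScenario):
        for name in ("kd_M", "ptot_M", "top_M", "dilution_factor",
                     "n_capillaries", "f0", "amp_unbound", "amp_bound",
                     "tau_s", "noise_sd"):
            rows.append({"id": "mst", "model": "tjump_1to1",
                         "parameter": name, "value": getattr(scenario, name)})
    else:
        raise TypeError(f"unknown scenario type {type(scenario).__name__}")
    return pd.DataFrame(rows)
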