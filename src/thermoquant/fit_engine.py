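"""Shared nonlinear least-squares machinery.

All model fits in the package go through :func:`nls_fit`: bounded
Levenberg/trust-region least squares (scipy), asymptotic standard errors from
the Jacobian covariance scaled by the residual variance, 95% confidence
intervals as estimate +/- 1.96 SE, and the quality-filter flags used to screen
fits (relative error > 50% on thermodynamic parameters, estimates too close to
their bounds, non-convergence, constant input signal).

Fits are deterministic: the same inputs always produce the same ModelFit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .preprocess import derivative, smooth_spikes

Z95 = 1.959963984540054  # two-sided 95% normal quantile

FLAG_REL_ERR = "REL_ERR_GT_50"
FLAG_NEAR_BOUNDARY = "NEAR_BOUNDARY"
FLAG_NOT_CONVERGED = "NOT_CONVERGED"
FLAG_CONSTANT = "CONSTANT_SIGNAL"
FLAG_LOW_AMPLITUDE = "LOW_AMPLITUDE"
FLAG_NO_SHIFT = "NO_SHIFT"

#: the full quality-flag vocabulary used in result tables
FLAG_VOCABULARY = frozenset({
    FLAG_REL_ERR, FLAG_NEAR_BOUNDARY, FLAG_NOT_CONVERGED, FLAG_CONSTANT,
    FLAG_LOW_AMPLITUDE, FLAG_NO_SHIFT,
})


@dataclass
class FitBounds:
    """Box bounds per parameter plus the boundary-proximity tolerance.

    ``boundary_tol_frac`` is the fraction of the bound span within which an
    estimate counts as "too close" to a bound (default 1%).
    """

    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    boundary_tol_frac: float = 0.01

    def __post_init__(self):
        for name in set(self.lower) & set(self.upper):
            if not self.lower[name] < self.upper[name]:
                raise ValueError(f"bounds for {name!r}: lower must be < upper")

    def lo(self, name: str) -> float:
        return self.lower.get(name, -np.inf)

    def hi(self, name: str) -> float:
        return self.upper.get(name, np.inf)

    def arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([self.lo(n) for n in names]),
                np.array([self.hi(n) for n in names]))


@dataclass
class ModelFit:
    """Result of a nonlinear least-squares fit.

    ``params``/``std_errors`` are keyed by parameter name.  Relative errors
    are ``100*|SE/estimate|`` and CI95 is ``estimate +/- 1.96*SE`` for every
    directly fitted parameter.  ``derived`` holds transformed quantities
    (e.g. linear-scale Kd from a log-scale fit) as
    ``name -> (estimate, ci_low, ci_high)``; their intervals may be
    asymmetric and they carry no standard error of their own.
    """

    model: str
    params: dict[str, float]
    std_errors: dict[str, float]
    covariance: np.ndarray | None
    residual_rms: float
    converged: bool
    n_points: int
    flags: set[str] = field(default_factory=set)
    derived: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def rel_errors_pct(self) -> dict[str, float]:
        out = {}
        for name, est in self.params.items():
            se = self.std_errors.get(name, math.nan)
            out[name] = 100.0 * abs(se / est) if est != 0 else math.inf
        return out

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        return {
            name: (est - Z95 * self.std_errors.get(name, math.nan),
                   est + Z95 * self.std_errors.get(name, math.nan))
            for name, est in self.params.items()
        }

    def result_rows(self, fit_id: str) -> list[dict]:
        flags = ";".join(sorted(self.flags))
        rows = []
        rel = self.rel_errors_pct
        ci = self.ci95
        for name, est in self.params.items():
            rows.append({
                "fit_id": fit_id, "model": self.model, "parameter": name,
                "estimate": est, "std_error": self.std_errors.get(name, math.nan),
                "rel_error_pct": rel[name],
                "ci95_low": ci[name][0], "ci95_high": ci[name][1],
                "flags": flags,
            })
        for name, (est, lo, hi) in self.derived.items():
            rows.append({
                "fit_id": fit_id, "model": self.model, "parameter": name,
                "estimate": est, "std_error": math.nan, "rel_error_pct": math.nan,
                "ci95_low": lo, "ci95_high": hi, "flags": flags,
            })
        return rows


def _constant_fit(model: str, initial: Mapping[str, float], n: int) -> ModelFit:
    return ModelFit(
        model=model,
        params=dict(initial),
        std_errors={k: math.nan for k in initial},
        covariance=None,
        residual_rms=math.nan,
        converged=False,
        n_points=n,
        flags={FLAG_CONSTANT},
    )


def nls_fit(
    model_fn: Callable[[np.ndarray, Mapping[str, float]], np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    initial: Mapping[str, float],
    bounds: FitBounds | None = None,
    model_name: str = "model",
    max_nfev: int = 2000,
) -> ModelFit:
    """Bounded least-squares fit of ``model_fn(x, params)`` to ``y``.

    Standard errors come from the Jacobian-based covariance scaled by the
    residual variance.  Non-convergence yields a ModelFit carrying the
    NOT_CONVERGED flag (after one deterministic restart from a perturbed
    start), never an exception.  A constant input signal yields the
    CONSTANT_SIGNAL flag without fitting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("data must be finite")
    names = list(initial)
    if np.ptp(y) == 0:
        return _constant_fit(model_name, initial, y.size)
    bounds = bounds or FitBounds()
    lo, hi = bounds.arrays(names)
    p0 = np.array([float(initial[n]) for n in names])
    if np.any(p0 < lo) or np.any(p0 > hi):
        raise ValueError("initial parameters must lie within bounds")

    def residual(p):
        return model_fn(x, dict(zip(names, p))) - y

    res = least_squares(residual, p0, bounds=(lo, hi), max_nfev=max_nfev)
    if not res.success:
        # one deterministic restart: nudge toward the box midpoint (finite
        # bounds) or scale up slightly (unbounded parameters)
        mid = np.where(np.isfinite(lo) & np.isfinite(hi), 0.5 * (lo + hi),
                       p0 * 1.05 + 1e-3)
        p1 = np.clip(p0 + 0.25 * (mid - p0), lo, hi)
        res2 = least_squares(residual, p1, bounds=(lo, hi), max_nfev=max_nfev)
        if res2.cost < res.cost or res2.success:
            res = res2

    p_hat = res.x
    n, k = y.size, len(names)
    dof = n - k
    cov = None
    se = np.full(k, math.nan)
    if dof > 0:
        s2 = 2.0 * res.cost / dof
        jtj = res.jac.T @ res.jac
        cov = np.linalg.pinv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    fit = ModelFit(
        model=model_name,
        params=dict(zip(names, map(float, p_hat))),
        std_errors=dict(zip(names, map(float, se))),
        covariance=cov,
        residual_rms=float(np.sqrt(np.mean(res.fun ** 2))),
        converged=bool(res.success),
        n_points=n,
    )
    if not res.success:
        fit.flags.add(FLAG_NOT_CONVERGED)
    return fit


def apply_quality_filters(
    fit: ModelFit,
    bounds: FitBounds,
    thermo_params: Iterable[str] | None = None,
    rel_err_max_pct: float = 50.0,
) -> ModelFit:
    """Flag fits whose parameters are poorly determined or sit on a bound.

    REL_ERR_GT_50 is raised when any thermodynamic parameter (baselines are
    exempt: their near-zero slopes legitimately have huge relative errors)
    has a relative standard error above ``rel_err_max_pct``.  NEAR_BOUNDARY is
    raised when any estimate lies within ``boundary_tol_frac`` of the bound
    span of either (finite) bound.
    """
    thermo = set(thermo_params) if thermo_params is not None else set(fit.params)
    rel = fit.rel_errors_pct
    if any(rel[name] > rel_err_max_pct for name in thermo if name in rel):
        fit.flags.add(FLAG_REL_ERR)  # NaN compares False; inf (estimate 0) flags
    tol = bounds.boundary_tol_frac
    for name, est in fit.params.items():
        lo, hi = bounds.lo(name), bounds.hi(name)
        if math.isfinite(lo) and math.isfinite(hi):
            span = hi - lo
            if est - lo <= tol * span or hi - est <= tol * span:
                fit.flags.add(FLAG_NEAR_BOUNDARY)
                break
    return fit


def initial_guess_two_state(
    temperature_K: np.ndarray, trace: np.ndarray
) -> dict[str, float]:
    """Seed a two-state melt fit from the data.

    Tm guess: temperature of max |dS/dT| after a light median smooth; if the
    derivative carries no transition signature (flat/linear trace) the guess
    falls back to the grid midpoint (the fit is then typically flagged).
    Baselines: least-squares lines over the first and last 10% of points
    (intercepts referenced to the first temperature of the range).
    dHu guess: 300 kJ/mol, a typical protein unfolding enthalpy.
    """
    t = np.asarray(temperature_K, dtype=float)
    y = np.asarray(trace, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 points for an initial guess")
    smoothed = smooth_spikes(y, 3)
    dy = derivative(smoothed, t)
    mag = np.abs(dy[1:-1])  # interior only; endpoints are one-sided
    scale = np.ptp(y) / (t[-1] - t[0])
    if np.ptp(mag) <= 1e-8 * max(scale, 1e-300):
        tm = 0.5 * (t[0] + t[-1])  # no transition signature
    else:
        tm = float(t[1 + int(np.argmax(mag))])
    n_edge = max(2, t.size // 10)
    tref = t[0]
    kN, bN = np.polyfit(t[:n_edge] - tref, y[:n_edge], 1)
    kU, bU = np.polyfit(t[-n_edge:] - tref, y[-n_edge:], 1)
    return {"dHu": 3.0e5, "Tm": tm, "bN": float(bN), "kN": float(kN),
            "bU": float(bU), "kU": float(kU)}
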