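"""Signal preprocessing applied before fitting.

Temperature-range restriction, spike removal by rolling median, optional
Savitzky-Golay smoothing, min-max normalization and finite-difference
derivatives.  Derivatives are for display and initial guesses only; the
thermodynamic models are always fitted to the signal itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io_formats import MeltCurveSet


@dataclass
class PreprocessConfig:
    """Preprocessing choices for a melt dataset.

    ``t_min_K``/``t_max_K`` give the inclusive temperature range of interest;
    ``smooth_window`` is the odd rolling-median window (>3 adds a
    Savitzky-Golay pass); ``normalize`` applies min-max scaling per well.
    """

    t_min_K: float = -np.inf
    t_max_K: float = np.inf
    smooth: bool = False
    smooth_window: int = 3
    normalize: bool = False

    def __post_init__(self):
        if not self.t_min_K < self.t_max_K:
            raise ValueError("t_min_K must be < t_max_K")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 3")


def restrict_range(mcs: MeltCurveSet, t_min_K: float, t_max_K: float) -> MeltCurveSet:
    """Keep only grid points with ``t_min_K <= T <= t_max_K`` (inclusive).

    At least 5 grid points must survive; annotations are preserved.
    """
    mask = (mcs.temperature_K >= t_min_K) & (mcs.temperature_K <= t_max_K)
    if mask.sum() < 5:
        raise ValueError(
            f"temperature range [{t_min_K:g}, {t_max_K:g}] K keeps only "
            f"{int(mask.sum())} grid points (need >= 5)"
        )
    return MeltCurveSet(
        mcs.temperature_K[mask],
        mcs.signals[:, mask],
        list(mcs.well_ids),
        mcs.annotations.copy(),
        mcs.channel,
    )


def smooth_spikes(trace: np.ndarray, window: int = 3) -> np.ndarray:
    """Rolling-median pass that removes isolated spikes.

    The window shrinks symmetrically at the edges, so a strictly linear trace
    is returned unchanged.  Output length equals input length.
    """
    trace = np.asarray(trace, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3 or window > trace.size:
        raise ValueError("window must be >= 3 and <= trace length")
    half = window // 2
    out = np.empty_like(trace)
    n = trace.size
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(trace[i - h:i + h + 1])
    return out


def smooth_trace(trace: np.ndarray, window: int = 3) -> np.ndarray:
    """Spike removal plus, for windows > 3, a Savitzky-Golay noise pass.

    The median pass (window 3) kills single-point spikes without biasing the
    transition; the optional polynomial pass (order 3) reduces broadband noise.
    """
    out = smooth_spikes(trace, 3)
    if window > 3:
        w = min(window, out.size if out.size % 2 else out.size - 1)
        out = savgol_filter(out, w, polyorder=min(3, w - 1))
    return out


def minmax_normalize(trace: np.ndarray) -> np.ndarray:
    """Affine map of a trace onto [0, 1] (min -> 0, max -> 1)."""
    trace = np.asarray(trace, dtype=float)
    lo, hi = trace.min(), trace.max()
    if hi <= lo:
        raise ValueError("cannot min-max normalize a constant trace")
    return (trace - lo) / (hi - lo)


def derivative(trace: np.ndarray, temperature_K: np.ndarray) -> np.ndarray:
    """dS/dT by central differences on a (possibly non-uniform) grid.

    Endpoints use one-sided differences.  Used for plots and for locating the
    melting transition (max |dS/dT|) when seeding fits.
    """
    trace = np.asarray(trace, dtype=float)
    temperature_K = np.asarray(temperature_K, dtype=float)
    if trace.size < 5:
        raise ValueError("need at least 5 points for a derivative")
    return np.gradient(trace, temperature_K)


def apply_config(mcs: MeltCurveSet, config: PreprocessConfig) -> MeltCurveSet:
    """Run range restriction, smoothing and normalization in the standard order."""
    out = restrict_range(mcs, config.t_min_K, config.t_max_K)
    sig = out.signals.copy()
    for i in range(sig.shape[0]):
        if config.smooth:
            sig[i] = smooth_trace(sig[i], config.smooth_window)
        if config.normalize:
            sig[i] = minmax_normalize(sig[i])
    return MeltCurveSet(out.temperature_K, sig, list(out.well_ids),
                        out.annotations.copy(), out.channel)
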