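"""Pyrene-actin polymerization kinetics and concentration-response fitting.

The polymerization rate of a reaction is summarized as the maximal slope of
the fluorescence curve over a sliding window (robust to the lag phase).
Slopes measured across activator concentrations are fitted with a one-site
saturation (hyperbolic) model ``slope = vmax * c / (c + k_half)``, through
the origin, yielding the half-maximal activating concentration with
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit

from .exceptions import FitError, InputError

__all__ = [
    "PolymerizationCurve",
    "ConcentrationResponse",
    "max_slope",
    "fit_halfmax",
]

# reagent concentrations shared by all polymerization reactions
DEFAULT_REAGENTS = {
    "actin_uM": 3.0,
    "arp23_nM": 25.0,
    "nwasp_nM": 50.0,
    "liposomes_uM": 12.5,
}


@dataclass
class PolymerizationCurve:
    """One pyrene fluorescence time course."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    condition: str = ""
    reagents: dict = field(default_factory=lambda: dict(DEFAULT_REAGENTS))

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.shape != self.fluorescence.shape:
            raise InputError("time and fluorescence must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise InputError("time must be strictly increasing")

    def max_slope(self, window_points: int = 11) -> float:
        return max_slope(self.time_s, self.fluorescence, window_points)


@dataclass
class ConcentrationResponse:
    """Fitted one-site saturation response; the curve passes through (0, 0)."""

    concentrations: np.ndarray
    slopes: np.ndarray
    vmax: float
    k_half: float
    vmax_ci: tuple[float, float]
    k_half_ci: tuple[float, float]
    residuals: np.ndarray

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.vmax * c / (c + self.k_half)


def max_slope(
    time_s: np.ndarray,
    fluorescence: np.ndarray,
    window_points: int = 11,
) -> float:
    """Maximum least-squares slope of the curve over all sliding windows of
    ``window_points`` samples (fluorescence units per second)."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InputError("time and fluorescence must be equal-length 1-D arrays")
    if t.size < window_points:
        raise InputError(
            f"curve has {t.size} points; window needs {window_points}"
        )
    if window_points < 2:
        raise InputError("window_points must be >= 2")
    tw = sliding_window_view(t, window_points)
    yw = sliding_window_view(y, window_points)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    return float(slopes.max())


def _hyperbola(c: np.ndarray, vmax: float, k_half: float) -> np.ndarray:
    return vmax * c / (c + k_half)


def fit_halfmax(
    concentrations: np.ndarray,
    slopes: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ConcentrationResponse:
    """Least-squares fit of ``slope = vmax * c / (c + k_half)``.

    Requires at least 4 distinct concentrations.  Bootstrap (case
    resampling) percentile intervals are reported for both parameters.
    Raises :class:`FitError` on non-convergence, an unidentifiable
    response (all slopes equal), or a half-max estimate more than 10x
    outside the measured concentration range.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(slopes, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise InputError("concentrations and slopes must be equal-length 1-D arrays")
    if np.any(c < 0):
        raise InputError("concentrations must be non-negative")
    if np.unique(c).size < 4:
        raise InputError("need at least 4 distinct concentrations")
    positive = y[c > 0]
    if positive.size and np.ptp(positive) <= 1e-12 * max(np.abs(positive).max(), 1.0):
        raise FitError("slopes are constant across concentrations; k_half unidentifiable")

    def _fit(ci: np.ndarray, yi: np.ndarray) -> tuple[float, float]:
        vmax0 = float(yi.max())
        half = 0.5 * vmax0
        above = ci[yi >= half]
        k0 = float(above.min()) if above.size else float(np.median(ci[ci > 0]))
        popt, _ = curve_fit(
            _hyperbola,
            ci,
            yi,
            p0=[vmax0, max(k0, 1e-9)],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
        return float(popt[0]), float(popt[1])

    try:
        vmax, k_half = _fit(c, y)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"saturation fit failed to converge: {exc}") from exc
    if k_half > 10.0 * c.max():
        raise FitError(
            f"k_half {k_half:.3g} lies far outside the measured range "
            f"(max concentration {c.max():.3g})"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot_v, boot_k = [], []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, c.size, size=c.size)
        if np.unique(c[idx]).size < 4:
            continue
        try:
            bv, bk = _fit(c[idx], y[idx])
        except (RuntimeError, ValueError):
            continue
        boot_v.append(bv)
        boot_k.append(bk)
    if boot_v:
        vmax_ci = tuple(np.percentile(boot_v, [2.5, 97.5]))
        k_half_ci = tuple(np.percentile(boot_k, [2.5, 97.5]))
    else:
        vmax_ci = (np.nan, np.nan)
        k_half_ci = (np.nan, np.nan)

    residuals = y - _hyperbola(c, vmax, k_half)
    return ConcentrationResponse(c, y, vmax, k_half, vmax_ci, k_half_ci, residuals)


def fit_halfmax_table(response: pd.DataFrame, **kwargs) -> ConcentrationResponse:
    """Convenience wrapper for tables with ``concentration`` and ``slope``
    columns (e.g. the output of the slope-response simulator)."""
    return fit_halfmax(
        response["concentration"].to_numpy(), response["slope"].to_numpy(), **kwargs
    )
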