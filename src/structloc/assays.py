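"""Thermal-shift melting analysis and ligand-binding curve fits.

Melting temperatures are read from the first derivative of the normalized
dye-fluorescence melt curve (unfolding raises reporter fluorescence, so a
transition is a maximum of +dF/dT); multiple transitions are detected by
peak prominence. Binding assays are fit as one-site hyperbolic saturation
(Kd, Bmax) and single-exponential dissociation (koff = 1/tau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .errors import FitFailureError


@dataclass
class MeltCurve:
    """Temperature-indexed fluorescence from a thermal-shift assay."""

    temperatures: np.ndarray  # °C, strictly increasing
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if len(self.temperatures) != len(self.fluorescence):
            raise ValueError("temperature and fluorescence lengths differ")
        if len(self.temperatures) < 10:
            raise ValueError("melt curve needs >= 10 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(self.temperatures))
                and np.all(np.isfinite(self.fluorescence))):
            raise ValueError("melt curve values must be finite")


@dataclass
class MeltResult:
    tms: list[float]                      # °C, ascending
    derivative_curve: np.ndarray          # (N, 2): temperature, dF/dT
    n_transitions: int = 0

    def __post_init__(self):
        self.n_transitions = len(self.tms)


@dataclass
class BindingSeries:
    """Concentration- (saturation) or time- (dissociation) indexed signal."""

    x: np.ndarray
    signal: np.ndarray
    fitted: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.signal = np.asarray(self.signal, float)
        if len(self.x) != len(self.signal):
            raise ValueError("x and signal lengths differ")
        if np.any(self.x < 0):
            raise ValueError("x must be non-negative")


def _quadratic_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid peak position by parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = x[i + 1] - x[i]
    return float(x[i] + np.clip(delta, -0.5, 0.5) * step)


def melting_temperatures(curve: MeltCurve, smooth_window: int = 7,
                         min_prominence: float = 0.1) -> MeltResult:
    """Tm values from the normalized first-derivative melt curve.

    Fluorescence is min-max normalized to [0, 1] and smoothed with a local
    polynomial (Savitzky-Golay, order 2); dF/dT comes from central
    differences. Tm values are derivative maxima with prominence at least
    ``min_prominence`` x the derivative range, restricted to temperatures
    before the global fluorescence maximum (excluding post-aggregation
    decay). A curve with no transitions yields an empty list.
    """
    if smooth_window % 2 == 0 or smooth_window < 3 or smooth_window >= len(curve.temperatures):
        raise ValueError("smooth_window must be odd, >= 3 and < curve length")
    temp = curve.temperatures
    flo, fhi = curve.fluorescence.min(), curve.fluorescence.max()
    if fhi - flo <= 0:
        deriv = np.zeros_like(temp)
        return MeltResult(tms=[], derivative_curve=np.column_stack([temp, deriv]))
    norm = (curve.fluorescence - flo) / (fhi - flo)
    smooth = savgol_filter(norm, smooth_window, 2)
    deriv = np.gradient(smooth, temp)
    # restrict to the rising region before the global fluorescence maximum
    i_max = int(np.argmax(smooth))
    region = deriv[:i_max + 1]
    if len(region) < 3 or np.all(region <= 0):
        return MeltResult(tms=[], derivative_curve=np.column_stack([temp, deriv]))
    rng = float(region.max() - region.min())
    peaks, _ = find_peaks(region, prominence=min_prominence * rng)
    tms = sorted(_quadratic_peak(temp, deriv, int(p)) for p in peaks)
    return MeltResult(tms=tms, derivative_curve=np.column_stack([temp, deriv]))


def _hyperbola(c, bmax, kd, baseline):
    return bmax * c / (kd + c) + baseline


def fit_saturation(series: BindingSeries) -> BindingSeries:
    """One-site saturation fit: signal = Bmax*c/(Kd + c) + baseline.

    Deterministic initialization: baseline from the lowest signal, Bmax from
    the signal span, Kd from the concentration nearest half-saturation.
    Standard errors come from the residual-based covariance. Data with no
    saturation curvature fit with a warning and wide errors rather than
    failing.
    """
    if len(series.x) < 5:
        raise FitFailureError("saturation fit needs >= 5 concentration points")
    c, y = series.x, series.signal
    baseline0 = float(y.min())
    bmax0 = float(y.max() - y.min())
    if bmax0 <= 0:
        raise FitFailureError("signal shows no concentration dependence")
    half = baseline0 + 0.5 * bmax0
    kd0 = float(c[np.argmin(np.abs(y - half))])
    kd0 = max(kd0, 1e-12)
    try:
        popt, pcov = curve_fit(_hyperbola, c, y, p0=[bmax0, kd0, baseline0],
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"saturation fit failed: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    bmax, kd, baseline = popt
    if kd <= 0:
        raise FitFailureError("fitted Kd is non-positive")
    residual_scale = float(np.sqrt(np.mean((_hyperbola(c, *popt) - y) ** 2)))
    essentially_exact = residual_scale < 1e-9 * max(np.ptp(y), 1e-300)
    if not essentially_exact and (
            not np.all(np.isfinite(perr)) or perr[1] > 10 * abs(kd)
            or kd > 10 * c.max()):
        warnings.warn("saturation fit is ill-conditioned (no curvature in the "
                      "sampled range?); parameter errors are wide", stacklevel=2)
    series.fitted = {
        "kd": float(kd), "bmax": float(bmax), "baseline": float(baseline),
        "kd_err": float(perr[1]), "bmax_err": float(perr[0]),
        "baseline_err": float(perr[2]),
    }
    return series


def _exp_decay(t, amplitude, tau, baseline):
    return amplitude * np.exp(-t / tau) + baseline


def fit_dissociation(series: BindingSeries) -> BindingSeries:
    """Single-exponential dissociation: signal = A*exp(-t/tau) + baseline.

    koff = 1/tau. Initialization comes from log-linear regression on
    baseline-subtracted data. Raises on non-decaying data.
    """
    if len(series.x) < 6:
        raise FitFailureError("dissociation fit needs >= 6 time points")
    if not np.all(np.diff(series.x) > 0):
        raise ValueError("time points must be strictly increasing")
    t, y = series.x, series.signal
    n = len(y)
    if np.mean(y[: max(n // 3, 1)]) <= np.mean(y[-max(n // 3, 1):]):
        raise FitFailureError("signal does not decay; cannot fit dissociation")
    baseline0 = float(y.min()) - 1e-12
    z = y - baseline0
    pos = z > 0
    slope, intercept = np.polyfit(t[pos], np.log(z[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 2.0
    amp0 = float(np.exp(intercept))
    try:
        popt, pcov = curve_fit(_exp_decay, t, y, p0=[amp0, tau0, baseline0],
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"dissociation fit failed: {exc}") from exc
    amplitude, tau, baseline = popt
    if tau <= 0:
        raise FitFailureError("fitted time constant is non-positive")
    perr = np.sqrt(np.diag(pcov))
    series.fitted = {
        "tau": float(tau), "koff": float(1.0 / tau),
        "amplitude": float(amplitude), "baseline": float(baseline),
        "tau_err": float(perr[1]), "amplitude_err": float(perr[0]),
        "baseline_err": float(perr[2]),
        "koff_err": float(perr[1] / tau**2),
    }
    return series
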