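"""Thermal-stability and kinetic characterization fits.

Covers the standard quantitative read-outs used to compare an engineered
enzyme with its wild type: first-order thermal-inactivation half-life,
thermal tolerance midpoint (T50 after a fixed heat challenge), DSC melting
temperature by peak picking, Michaelis-Menten kinetics via the
double-reciprocal (Lineweaver-Burk) plot or direct nonlinear fit,
catalytic efficiency, and the fold-change / percent-change arithmetic used
to report improvements.

Units follow common enzymology practice for polymeric substrates: substrate
in mg/mL, rates in umol/(min.mg), kcat in 1/s (rate times molar mass in
kDa = mg/umol, divided by 60 s/min), and efficiency kcat/Km in mL/(s.mg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

LN2 = float(np.log(2.0))


@dataclass
class InactivationFit:
    k: float  # first-order rate constant, 1/min
    t_half: float  # min
    r_squared: float
    n_points: int


@dataclass
class ThermalToleranceFit:
    t50: float  # deg C
    slope: float  # transition width parameter, deg C
    method: str  # "logistic" | "interpolation"


@dataclass
class DSCFit:
    tm: float  # deg C
    peak_height: float  # baseline-subtracted heat capacity at the peak
    baseline: str  # description of the subtracted baseline


@dataclass
class KineticsFit:
    km: float  # mg/mL
    vmax: float  # umol/(min.mg)
    method: str  # "lineweaver_burk" | "nonlinear"
    kcat: float | None = None  # 1/s
    efficiency: float | None = None  # mL/(s.mg)


def fit_inactivation(times, residual_activity) -> InactivationFit:
    """First-order inactivation: least-squares of ln(activity) vs time.

    The intercept is free, so the fit is invariant to rescaling the
    activity units (e.g. normalizing by the untreated control).  The decay
    constant is the negated slope and the half-life is ln(2)/k.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(residual_activity, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(a <= 0):
        raise ValueError("activities must be positive for a log-linear fit")
    res = stats.linregress(t, np.log(a))
    if res.slope >= 0:
        raise ValueError("no measurable inactivation (non-negative slope)")
    k = -float(res.slope)
    return InactivationFit(k=k, t_half=LN2 / k, r_squared=float(res.rvalue**2),
                           n_points=int(t.size))


def normalize_activity(raw, control: float) -> np.ndarray:
    """Raw activity units to fractions of the untreated control."""
    if control <= 0:
        raise ValueError("control activity must be positive")
    return np.asarray(raw, dtype=float) / control


def fold_change(value_mut: float, value_wt: float, convention: str = "ratio") -> float:
    """mut/wt ratio, or the "increased N-fold" convention mut/wt - 1."""
    if value_wt <= 0:
        raise ValueError("wild-type value must be positive")
    ratio = value_mut / value_wt
    if convention == "ratio":
        return ratio
    if convention == "increase":
        return ratio - 1.0
    raise ValueError(f"unknown convention {convention!r}")


def percent_change(mutant: float, wild: float) -> float:
    """Percent increase of the mutant over the wild type: 100 (mut/wt - 1)."""
    if wild <= 0:
        raise ValueError("wild-type value must be positive")
    return 100.0 * (mutant / wild - 1.0)


def _descending_logistic(T, t50, s):
    return 1.0 / (1.0 + np.exp((T - t50) / s))


def fit_t50(temperatures, residual_activity) -> ThermalToleranceFit:
    """Midpoint of the residual-activity-vs-temperature transition.

    Fits a two-parameter descending logistic ``a(T) = 1/(1+exp((T-t50)/s))``;
    if the fit cannot converge (or fewer than 4 points are given), falls
    back to linear interpolation between the two points bracketing 0.5,
    recording the method used.  Raises when the activities never cross 0.5
    within the measured range.
    """
    T = np.asarray(temperatures, dtype=float)
    a = np.asarray(residual_activity, dtype=float)
    order = np.argsort(T)
    T, a = T[order], a[order]
    if T.size < 2:
        raise ValueError("need at least 2 temperature points")
    if a.max() <= 0.5 or a.min() >= 0.5:
        raise ValueError("T50 out of range: activities never cross 0.5")

    if T.size >= 4:
        try:
            p0 = (float(T[np.argmin(np.abs(a - 0.5))]), 2.0)
            popt, _ = optimize.curve_fit(_descending_logistic, T, a, p0=p0,
                                         maxfev=10000)
            t50, s = float(popt[0]), float(popt[1])
            if T.min() <= t50 <= T.max() and s > 0:
                return ThermalToleranceFit(t50=t50, slope=s, method="logistic")
        except RuntimeError:
            pass

    # interpolation fallback: first pair of consecutive points bracketing 0.5
    for i in range(T.size - 1):
        lo, hi = a[i], a[i + 1]
        if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
            t50 = float(T[i] + (lo - 0.5) / (lo - hi) * (T[i + 1] - T[i]))
            width = float(T[i + 1] - T[i])
            return ThermalToleranceFit(t50=t50, slope=width, method="interpolation")
    raise ValueError("T50 out of range: no bracketing interval found")


def dsc_tm(temperature, heat_capacity, baseline_fraction: float = 0.10) -> DSCFit:
    """Melting temperature from a single-peak DSC thermogram.

    A straight baseline fitted through the first and last
    ``baseline_fraction`` of the scan is subtracted; Tm is the temperature
    of the maximum excess heat capacity, refined by fitting a parabola
    through the grid maximum and its neighbors.  A trace with no positive
    excursion above the baseline is rejected.
    """
    T = np.asarray(temperature, dtype=float)
    cp = np.asarray(heat_capacity, dtype=float)
    if T.size < 5:
        raise ValueError("need at least 5 scan points")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")

    span = T[-1] - T[0]
    window = (T <= T[0] + baseline_fraction * span) | (T >= T[-1] - baseline_fraction * span)
    slope, intercept = np.polyfit(T[window], cp[window], 1)
    excess = cp - (slope * T + intercept)

    resid_rms = float(np.sqrt(np.mean((excess[window]) ** 2)))
    imax = int(np.argmax(excess))
    peak = float(excess[imax])
    scale = max(abs(cp).max(), 1.0)
    if peak <= max(3.0 * resid_rms, 1e-9 * scale):
        raise ValueError("no transition: no positive excursion above baseline")

    tm = float(T[imax])
    if 0 < imax < T.size - 1:
        # parabola through the three points around the grid maximum
        x = T[imax - 1:imax + 2]
        y = excess[imax - 1:imax + 2]
        coeffs = np.polyfit(x, y, 2)
        if coeffs[0] < 0:
            vertex = -coeffs[1] / (2 * coeffs[0])
            if x[0] <= vertex <= x[2]:
                tm = float(vertex)
                peak = float(np.polyval(coeffs, vertex))
    baseline_desc = (f"linear through first/last {baseline_fraction:.0%} of scan "
                     f"({slope:.4g} T + {intercept:.4g})")
    return DSCFit(tm=tm, peak_height=peak, baseline=baseline_desc)


def _michaelis_menten(S, vmax, km):
    return vmax * S / (km + S)


def fit_michaelis_menten(substrate, rate, method: str = "lineweaver_burk") -> KineticsFit:
    """Km and Vmax from initial-rate data.

    ``lineweaver_burk``: unweighted ordinary least squares of 1/v on 1/S;
    Km = slope/intercept and Vmax = 1/intercept.  ``nonlinear``: direct
    least squares on v = Vmax S/(Km + S), seeded by the double-reciprocal
    estimate and weighted relatively (sigma proportional to v), which is
    the appropriate error model for rate assays whose noise is
    multiplicative.  Both are exact on noiseless data.  A non-positive
    double-reciprocal intercept means the data show no saturation in the
    substrate range.
    """
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if S.size < 4:
        raise ValueError("need at least 4 substrate-rate pairs")
    if np.any(S <= 0) or np.any(v <= 0):
        raise ValueError("substrate concentrations and rates must be positive")
    res = stats.linregress(1.0 / S, 1.0 / v)
    if res.intercept <= 0:
        raise ValueError("no saturation in range (non-positive 1/v intercept)")
    km_lb = float(res.slope / res.intercept)
    vmax_lb = float(1.0 / res.intercept)
    if method == "lineweaver_burk":
        return KineticsFit(km=km_lb, vmax=vmax_lb, method=method)
    if method == "nonlinear":
        popt, _ = optimize.curve_fit(_michaelis_menten, S, v, p0=(vmax_lb, km_lb),
                                     sigma=v, maxfev=10000)
        return KineticsFit(km=float(popt[1]), vmax=float(popt[0]), method=method)
    raise ValueError(f"unknown method {method!r}")


def catalytic_efficiency(vmax: float, km: float, molar_mass: float) -> tuple[float, float]:
    """kcat (1/s) and kcat/Km (mL/(s.mg)) from Vmax, Km, and molar mass.

    With Vmax in umol/(min.mg) and the molar mass in kDa (= mg/umol),
    ``kcat = vmax * molar_mass / 60`` and ``efficiency = kcat / km``.
    """
    if vmax <= 0 or km <= 0 or molar_mass <= 0:
        raise ValueError("vmax, km and molar mass must be positive")
    kcat = vmax * molar_mass / 60.0
    return kcat, kcat / km


def complete_kinetics(fit: KineticsFit, molar_mass: float) -> KineticsFit:
    """Fill in kcat and efficiency on an existing Km/Vmax fit."""
    kcat, eff = catalytic_efficiency(fit.vmax, fit.km, molar_mass)
    return KineticsFit(km=fit.km, vmax=fit.vmax, method=fit.method,
                       kcat=kcat, efficiency=eff)
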