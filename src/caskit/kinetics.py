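"""Quantitative models and fits for cleavage, collateral-nuclease and binding assays.

Closed forms implemented here:

* gel densitometry:  fraction cleaved (%) = 100 * Ip / (Ip + Is)
* capillary electrophoresis: same ratio over peak areas, after discarding
  peaks below a minimum RFU height (default 50)
* single exponential association: fraction cleaved = A * (1 - exp(-k t))
* fluorophore-quencher (FQ) reporter conversion:
  c_cl = (F_t - F_uncleaved(c0)) / (S_cl - S_ucl), with the two slopes taken
  from linear standard curves of fully-cleaved and uncleaved reporter, and
  the fraction form 100 * F_t / F_cleaved
* Michaelis-Menten: v = Vmax * X / (KM + X), kcat = Vmax / E,
  efficiency = kcat / KM
* tight-binding (quadratic) isotherm:
  bound = 0.5 * ((Kd + x + S) - sqrt((Kd + x + S)^2 - 4 x S))

All fits are bounded least squares with a small multi-start to avoid local
minima, and are exact (to optimizer tolerance) on noise-free data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

#: FQ reporter concentration grid used for Michaelis-Menten velocity
#: measurements: 0.001, 0.01, 0.1, 0.2, 0.5, 1, 2 uM (molar).
REPORTER_CONCENTRATIONS_M: tuple[float, ...] = (
    1e-9, 1e-8, 1e-7, 2e-7, 5e-7, 1e-6, 2e-6)

#: The comparator enzyme's grid adds one 0.05 uM point.
REPORTER_CONCENTRATIONS_WITH_50NM_M: tuple[float, ...] = tuple(sorted(
    REPORTER_CONCENTRATIONS_M + (5e-8,)))

#: Effective RNP-activator complex concentration in the collateral assay (0.1 nM).
EFFECTIVE_COMPLEX_CONC_M: float = 1e-10

#: Labeled oligoduplex concentration in the mobility-shift assay (2 nM).
EMSA_SUBSTRATE_CONC_M: float = 2e-9

#: Minimum peak height (relative fluorescence units) for CE peak detection.
CE_MIN_RFU: float = 50.0

#: Published collateral ssDNase turnover constants used as generator settings
#: for recovery fixtures: kcat in molecules s^-1, kcat/KM in s^-1 M^-1,
#: keyed by enzyme then activator type.
COLLATERAL_CONSTANTS: dict[str, dict[str, dict[str, float]]] = {
    "Asp2Cas12l": {
        "ssDNA": {"kcat": 0.44, "efficiency": 6.5e5},
        "dsDNA": {"kcat": 0.41, "efficiency": 4.2e5},
    },
    "LbCas12a": {
        "ssDNA": {"kcat": 1.47, "efficiency": 3.9e7},
        "dsDNA": {"kcat": 1.33, "efficiency": 2.6e7},
    },
}


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def exponential_association(t, A, k):
    """A * (1 - exp(-k t))."""
    t = np.asarray(t, dtype=float)
    return A * (1.0 - np.exp(-k * t))


def michaelis_menten(X, vmax, km):
    """vmax * X / (km + X)."""
    X = np.asarray(X, dtype=float)
    return vmax * X / (km + X)


def binding_isotherm(x, kd, S):
    """Tight-binding quadratic: bound concentration at RNP concentration x.

    Never exceeds min(x, S); at kd = 0 it equals min(x, S) exactly, and
    saturates to S as x grows.
    """
    x = np.asarray(x, dtype=float)
    b = kd + x + S
    disc = np.maximum(b * b - 4.0 * x * S, 0.0)
    return 0.5 * (b - np.sqrt(disc))


# ---------------------------------------------------------------------------
# Intensity ratios
# ---------------------------------------------------------------------------

def fraction_cleaved_gel(i_products: float, i_substrate: float) -> float:
    """Percent cleaved from gel band intensities: 100 * Ip / (Ip + Is)."""
    if i_products < 0 or i_substrate < 0:
        raise ValueError("band intensities must be >= 0")
    total = i_products + i_substrate
    if total == 0:
        raise ValueError("fraction cleaved undefined: both band intensities are zero")
    return 100.0 * i_products / total


@dataclass(frozen=True)
class CePeak:
    """One capillary-electrophoresis peak: integrated area, RFU height, role."""

    area: float
    rfu: float
    role: str  # "substrate" or "product"

    def __post_init__(self) -> None:
        if self.area < 0 or self.rfu < 0:
            raise ValueError("peak area and RFU must be >= 0")
        if self.role not in ("substrate", "product"):
            raise ValueError(f"peak role must be substrate/product, got {self.role!r}")


def ce_cleavage_percent(peaks: Sequence[CePeak], min_rfu: float = CE_MIN_RFU) -> float:
    """Percent cleaved from CE peak areas, excluding peaks below ``min_rfu``.

    Returns 100 * sum(product areas) / (substrate area + sum(product areas)).
    """
    kept = [p for p in peaks if p.rfu >= min_rfu]
    if not kept:
        raise ValueError(f"no peaks at or above the minimum RFU of {min_rfu}")
    prod = sum(p.area for p in kept if p.role == "product")
    subs = sum(p.area for p in kept if p.role == "substrate")
    if prod + subs == 0:
        raise ValueError("all surviving peaks have zero area")
    return 100.0 * prod / (subs + prod)


# ---------------------------------------------------------------------------
# Fit result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpFit:
    """Exponential-association fit: amplitude A, rate k (time^-1)."""

    A: float
    k: float
    residual_ss: float
    n: int
    flags: tuple[str, ...] = ()

    def predict(self, t):
        return exponential_association(t, self.A, self.k)


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence-vs-concentration standard curve."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, conc):
        return self.intercept + self.slope * np.asarray(conc, dtype=float)


@dataclass(frozen=True)
class FqConversion:
    """FQ fluorescence trace converted to cleaved-substrate concentrations."""

    concentrations: np.ndarray = field(repr=False)
    n_clipped: int
    c0: float
    cleaved_curve: StandardCurve
    uncleaved_curve: StandardCurve


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit with derived turnover and efficiency.

    ``kcat * enzyme_conc == vmax`` holds exactly by construction.
    """

    vmax: float
    km: float
    enzyme_conc: float
    residual_ss: float
    n: int
    flags: tuple[str, ...] = ()

    @property
    def kcat(self) -> float:
        return self.vmax / self.enzyme_conc

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat / KM (conc^-1 time^-1)."""
        return self.kcat / self.km

    def predict(self, X):
        return michaelis_menten(X, self.vmax, self.km)


@dataclass(frozen=True)
class BindingFit:
    """Tight-binding Kd fit with a residual-variance confidence interval."""

    kd: float
    kd_ci: tuple[float, float]
    substrate_conc: float
    residual_ss: float
    n: int

    def predict(self, x):
        return binding_isotherm(x, self.kd, self.substrate_conc)


@dataclass(frozen=True)
class LinearVelocity:
    """Initial velocity from a linear fit over the early part of a trace."""

    v0: float
    intercept: float
    r_squared: float
    window_n: int


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _multistart_fit(fn, x, y, starts, bounds):
    """Bounded least squares over several initial guesses; best SSR wins."""
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(fn, x, y, p0=p0, bounds=bounds,
                                   maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((fn(x, *popt) - y) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise RuntimeError("least-squares fit failed from every starting point")
    return best


def fit_exponential(t, y) -> ExpFit:
    """Fit A and k (k >= 0) in A * (1 - exp(-k t)) by bounded least squares."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(t < 0):
        raise ValueError("time values must be >= 0")

    flags: list[str] = []
    ymax = float(np.max(y))
    if ymax <= 0:
        # flat-zero (or nonpositive) trace: amplitude 0, rate unidentifiable
        return ExpFit(A=0.0, k=0.0, residual_ss=float(np.sum(y ** 2)),
                      n=t.size, flags=("degenerate_flat_trace",))

    tpos = t[t > 0]
    k_guess = 1.0 / float(np.median(tpos)) if tpos.size else 1.0
    starts = [(ymax, k_guess * f) for f in (0.2, 1.0, 5.0)]
    bounds = ([0.0, 0.0], [max(2.0 * ymax, 1e-9), np.inf])
    popt, _, ss = _multistart_fit(exponential_association, t, y, starts, bounds)
    A, k = float(popt[0]), float(popt[1])
    if k <= 1e-12:
        flags.append("rate_at_zero_boundary")
    return ExpFit(A=A, k=k, residual_ss=ss, n=t.size, flags=tuple(flags))


def fit_standard_curve(conc, fluorescence) -> StandardCurve:
    """Least-squares line through fluorescence vs concentration (>= 3 points)."""
    conc = np.asarray(conc, dtype=float)
    fl = np.asarray(fluorescence, dtype=float)
    if conc.size != fl.size:
        raise ValueError("conc and fluorescence must have equal length")
    if conc.size < 3:
        raise ValueError("standard curve needs at least 3 concentrations")
    slope, intercept = np.polyfit(conc, fl, 1)
    pred = intercept + slope * conc
    ss_res = float(np.sum((fl - pred) ** 2))
    ss_tot = float(np.sum((fl - fl.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept),
                         r_squared=r2, n=conc.size)


def convert_fluorescence(f_t, cleaved_curve: StandardCurve,
                         uncleaved_curve: StandardCurve, c0: float,
                         slope_rtol: float = 1e-6) -> FqConversion:
    """Convert an FQ fluorescence trace to cleaved-substrate concentrations.

    c_cl(t) = (F_t - F_uncleaved(c0)) / (S_cl - S_ucl), where F_uncleaved(c0)
    is the uncleaved standard line evaluated at the reporter concentration
    ``c0``. Values are clipped to [0, c0]; the number of clip events is
    reported. With equal intercepts this reduces to the plain slope-difference
    formula.
    """
    if c0 <= 0:
        raise ValueError("reporter concentration c0 must be > 0")
    denom = cleaved_curve.slope - uncleaved_curve.slope
    scale = max(abs(cleaved_curve.slope), abs(uncleaved_curve.slope), 1.0)
    if abs(denom) < slope_rtol * scale:
        raise ValueError(
            "cleaved and uncleaved standard-curve slopes are indistinguishable; "
            "the reporter does not resolve quenching")
    f_t = np.asarray(f_t, dtype=float)
    c = (f_t - uncleaved_curve.predict(c0)) / denom
    clipped = np.clip(c, 0.0, c0)
    n_clipped = int(np.sum(clipped != c))
    return FqConversion(concentrations=clipped, n_clipped=n_clipped, c0=c0,
                        cleaved_curve=cleaved_curve,
                        uncleaved_curve=uncleaved_curve)


def fq_fraction_cleaved(f_t, f_cleaved: float):
    """Fraction cleaved (%) = 100 * F_t / F_cleaved."""
    if f_cleaved <= 0:
        raise ValueError("fully-cleaved fluorescence must be > 0")
    return 100.0 * np.asarray(f_t, dtype=float) / f_cleaved


def initial_velocity(time_s, conc, window_n: int | None = None) -> LinearVelocity:
    """Initial velocity as the slope of a linear fit over the early trace.

    The window is the first ``max(5, 10% of points)`` samples unless given.
    """
    time_s = np.asarray(time_s, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if time_s.size != conc.size:
        raise ValueError("time and concentration must have equal length")
    if window_n is None:
        window_n = max(5, int(np.ceil(0.1 * time_s.size)))
    window_n = min(window_n, time_s.size)
    if window_n < 2:
        raise ValueError("initial-velocity window needs at least 2 points")
    tw, cw = time_s[:window_n], conc[:window_n]
    slope, intercept = np.polyfit(tw, cw, 1)
    pred = intercept + slope * tw
    ss_tot = float(np.sum((cw - cw.mean()) ** 2))
    r2 = 1.0 - float(np.sum((cw - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return LinearVelocity(v0=float(slope), intercept=float(intercept),
                          r_squared=r2, window_n=window_n)


def fit_michaelis_menten(conc, v0, enzyme_conc: float) -> MMFit:
    """Fit Vmax and KM (both > 0) and derive kcat = Vmax / E and kcat/KM.

    Requires at least 5 substrate concentrations. When every concentration
    sits far below the fitted KM the two parameters are individually
    unidentifiable (only their ratio is); the fit is flagged but the
    efficiency is still reported.
    """
    conc = np.asarray(conc, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if conc.size != v0.size:
        raise ValueError("conc and v0 must have equal length")
    if conc.size < 5:
        raise ValueError("need at least 5 substrate concentrations")
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be > 0")
    if np.any(conc <= 0):
        raise ValueError("substrate concentrations must be > 0")

    # rescale to O(1) so the optimizer converges at molar magnitudes
    x0 = float(np.max(conc))
    y0 = float(np.max(np.abs(v0))) or 1.0
    xs, ys = conc / x0, v0 / y0
    km_guess = float(np.median(xs))
    starts = [(1.0, km_guess * f) for f in (0.2, 1.0, 5.0)]
    bounds = ([0.0, 0.0], [np.inf, np.inf])
    popt, _, ss_scaled = _multistart_fit(michaelis_menten, xs, ys, starts, bounds)
    vmax, km = float(popt[0]) * y0, float(popt[1]) * x0
    ss = ss_scaled * y0 ** 2
    flags: list[str] = []
    if km > 10.0 * float(np.max(conc)):
        flags.append("km_unidentifiable")
    return MMFit(vmax=vmax, km=km, enzyme_conc=float(enzyme_conc),
                 residual_ss=ss, n=conc.size, flags=tuple(flags))


def intensities_to_bound(i_bound, i_free, c0: float = EMSA_SUBSTRATE_CONC_M):
    """Bound-substrate concentration from shifted/free band intensities.

    c_bound = I_bound / (I_bound + I_free) * c0.
    """
    i_bound = np.asarray(i_bound, dtype=float)
    i_free = np.asarray(i_free, dtype=float)
    total = i_bound + i_free
    if np.any(i_bound < 0) or np.any(i_free < 0):
        raise ValueError("band intensities must be >= 0")
    if np.any(total == 0):
        raise ValueError("bound fraction undefined where both intensities are zero")
    return i_bound / total * c0


def fit_binding(rnp_conc, c_bound, substrate_conc: float = EMSA_SUBSTRATE_CONC_M,
                tolerance: float = 0.05) -> BindingFit:
    """Fit Kd in the tight-binding quadratic isotherm (>= 5 RNP concentrations).

    Bound concentrations exceeding the substrate concentration by more than
    ``tolerance`` (relative) indicate inconsistent input and raise.
    """
    x = np.asarray(rnp_conc, dtype=float)
    y = np.asarray(c_bound, dtype=float)
    if x.size != y.size:
        raise ValueError("rnp_conc and c_bound must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 RNP concentrations")
    S = float(substrate_conc)
    if S <= 0:
        raise ValueError("substrate concentration must be > 0")
    if np.any(y > S * (1.0 + tolerance)):
        bad = float(np.max(y))
        raise ValueError(
            f"bound concentration {bad:g} exceeds substrate {S:g} beyond "
            f"tolerance; check intensity conversion")

    # fit in units of S so the parameter is O(1) at nanomolar scales
    xs, ys = x / S, y / S

    def model(xv, kd):
        return binding_isotherm(xv, kd, 1.0)

    kd_guess = float(np.median(xs))
    best = None
    for f in (0.1, 1.0, 10.0):
        try:
            popt, pcov = curve_fit(model, xs, ys, p0=(max(kd_guess * f, 1e-6),),
                                   bounds=([0.0], [np.inf]), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((model(xs, *popt) - ys) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise RuntimeError("binding fit failed from every starting point")
    popt, pcov, ss = best
    kd = float(popt[0]) * S
    ss *= S ** 2
    se = (float(np.sqrt(pcov[0, 0])) * S if np.all(np.isfinite(pcov))
          else float("nan"))
    ci = (max(kd - 1.96 * se, 0.0), kd + 1.96 * se) if np.isfinite(se) else (kd, kd)
    return BindingFit(kd=kd, kd_ci=ci, substrate_conc=S, residual_ss=ss, n=x.size)
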