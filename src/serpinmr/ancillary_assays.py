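"""Supporting biophysical assay fits.

Four small fitting routines accompany the NMR analysis:

* stoichiometry of inhibition (SI) from residual protease activity versus
  inhibitor:protease ratio, by linear extrapolation to zero activity;
* apparent ligand Kd from a fluorescence-polarisation titration, using the
  exact two-component quadratic binding isotherm (ligand depletion matters
  when the protein is titrated down to the probe concentration);
* translational diffusion coefficient from a pulsed-field-gradient decay
  via the Stejskal–Tanner equation;
* methyl-axis order parameter × correlation time (S²τc) from the
  cross-correlated-relaxation build-up of triple-quantum coherence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ActivityAssay",
    "BindingTitration",
    "DiffusionSeries",
    "BuildupSeries",
    "FitResult",
    "fit_si",
    "fit_fp_kd",
    "fit_diffusion",
    "fit_s2tc",
    "quadratic_bound_fraction",
    "tq_buildup_ratio",
    "GAMMA_H",
    "S2TC_ETA_COEFF",
]

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8


@dataclass
class FitResult:
    """Point estimate with standard error and the fitted curve parameters."""

    value: float
    stderr: float
    params: dict = field(default_factory=dict)


@dataclass
class ActivityAssay:
    """Residual protease activity (fraction) vs inhibitor:protease ratio."""

    ratios: np.ndarray
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if np.any(self.ratios < 0):
            raise ValueError("ratios must be >= 0")
        if np.any(self.activities < 0) or np.any(self.activities > 1.1):
            raise ValueError("activities must lie in [0, 1.1]")


@dataclass
class BindingTitration:
    """Polarisation signal vs total protein concentration (molar)."""

    concentrations: np.ndarray
    signals: np.ndarray
    probe_conc: float  # molar

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if np.any(self.concentrations < 0) or self.probe_conc <= 0:
            raise ValueError("concentrations must be non-negative, probe > 0")


@dataclass
class DiffusionSeries:
    """Integrated signal vs gradient strength (G/cm) for a PFG experiment."""

    gradients_G_per_cm: np.ndarray
    signals: np.ndarray
    delta_enc: float = 4e-3  # encoding gradient length δ, s
    Delta_diff: float = 100e-3  # diffusion delay Δ, s
    gamma_H: float = GAMMA_H

    def __post_init__(self) -> None:
        self.gradients_G_per_cm = np.asarray(self.gradients_G_per_cm, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.gradients_G_per_cm.size < 5:
            raise ValueError("need at least 5 gradient points")
        if np.any(self.signals <= 0):
            raise ValueError("signals must be positive")


@dataclass
class BuildupSeries:
    """Triple- and single-quantum intensities vs relaxation delay (s)."""

    delays: np.ndarray
    I_TQ: np.ndarray
    I_SQ: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.I_TQ = np.asarray(self.I_TQ, dtype=float)
        self.I_SQ = np.asarray(self.I_SQ, dtype=float)
        if np.any(self.delays <= 0):
            raise ValueError("delays must be positive")


# ---------------------------------------------------------------------------
# stoichiometry of inhibition


def fit_si(assay: ActivityAssay, activity_floor: float = 0.05) -> FitResult:
    """Stoichiometry of inhibition by linear extrapolation to zero activity.

    Ordinary least squares of ``activity = a + b·ratio`` on points with
    residual activity above ``activity_floor`` (excluding the saturated
    floor of the assay); SI is the x-intercept ``−a/b``, with standard
    error by first-order propagation from the OLS covariance.
    """
    mask = assay.activities > activity_floor
    x, y = assay.ratios[mask], assay.activities[mask]
    if x.size < 3:
        raise ValueError("need >= 3 points above the activity floor")
    X = np.column_stack([np.ones_like(x), x])
    coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = coef
    if b >= 0:
        raise ValueError("activity does not decrease with inhibitor: no SI")
    si = -a / b
    n = x.size
    resid = y - X @ coef
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    # d(si)/da = -1/b ; d(si)/db = a/b^2
    grad = np.array([-1.0 / b, a / b**2])
    se = float(np.sqrt(grad @ cov @ grad))
    return FitResult(value=float(si), stderr=se, params={"a": float(a), "b": float(b)})


# ---------------------------------------------------------------------------
# fluorescence polarisation binding


def quadratic_bound_fraction(P: np.ndarray, L: float, Kd: float) -> np.ndarray:
    """Exact bound fraction of probe for total protein P and total probe L."""
    P = np.asarray(P, dtype=float)
    s = P + L + Kd
    disc = np.maximum(s**2 - 4.0 * P * L, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * L)


def fit_fp_kd(titration: BindingTitration) -> FitResult:
    """Apparent Kd from an FP titration via the quadratic isotherm.

    Fits ``r(P) = r_free + (r_bound − r_free)·f_b(P; L, Kd)`` by nonlinear
    least squares in (r_free, r_bound, ln Kd); the log parameterisation
    keeps Kd positive without hard bounds.
    """
    P, r = titration.concentrations, titration.signals
    if P.size < 6:
        raise ValueError("need >= 6 titration points")
    L = titration.probe_conc
    span = r.max() - r.min()
    if span <= 0:
        raise ValueError("no signal transition in the titration range")

    def model(P, r_free, r_bound, ln_kd):
        return r_free + (r_bound - r_free) * quadratic_bound_fraction(
            P, L, math.exp(ln_kd)
        )

    # midpoint guess: concentration at half-signal
    order = np.argsort(P)
    half = r.min() + 0.5 * span
    idx = int(np.argmin(np.abs(r[order] - half)))
    kd0 = max(P[order][idx], L)
    p0 = [float(r[np.argmin(P)]), float(r[np.argmax(P)]), math.log(kd0)]
    popt, pcov = curve_fit(model, P, r, p0=p0, maxfev=20000)
    r_free, r_bound, ln_kd = popt
    kd = math.exp(ln_kd)
    kd_se = kd * math.sqrt(max(pcov[2, 2], 0.0))
    if not np.isfinite(pcov).all():
        warnings.warn("ill-conditioned FP fit: uncertainty unreliable")
    return FitResult(
        value=kd,
        stderr=kd_se,
        params={"r_free": float(r_free), "r_bound": float(r_bound)},
    )


# ---------------------------------------------------------------------------
# translational diffusion


def stejskal_tanner_b(series: DiffusionSeries) -> np.ndarray:
    """Gradient factor b = γ²g²δ²(Δ − δ/3) in s/m² for each gradient point."""
    g_T_per_m = series.gradients_G_per_cm * 1e-2  # 1 G/cm = 0.01 T/m
    return (
        series.gamma_H**2
        * g_T_per_m**2
        * series.delta_enc**2
        * (series.Delta_diff - series.delta_enc / 3.0)
    )


def fit_diffusion(series: DiffusionSeries) -> FitResult:
    """Diffusion coefficient (m²/s) from the Stejskal–Tanner decay.

    Nonlinear fit of ``I(g) = I0·exp(−D·b(g))``; a linearised ln(I) vs b
    slope provides the starting value. Non-decaying series are rejected.
    """
    b = stejskal_tanner_b(series)
    I = series.signals
    slope = np.polyfit(b, np.log(I), 1)[0]
    if slope >= 0:
        raise ValueError("signal does not decay with gradient strength")
    D0 = -slope

    def model(b, I0, D):
        return I0 * np.exp(-D * b)

    popt, pcov = curve_fit(model, b, I, p0=[float(I.max()), D0], maxfev=20000)
    D = float(popt[1])
    D_se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return FitResult(value=D, stderr=D_se, params={"I0": float(popt[0])})


# ---------------------------------------------------------------------------
# S²τc from triple-quantum build-up

# η = S2TC_ETA_COEFF × S²τc for an idealised CH3 group:
# (9/10) [P2(cos 90°)]² (μ0/4π · γH² ħ / r_HH³)² with r_HH = 1.813 Å.
_MU0_4PI = 1e-7  # T m / A
_HBAR = 1.054571817e-34  # J s
_R_HH = 1.813e-10  # m
S2TC_ETA_COEFF = 0.9 * 0.25 * (_MU0_4PI * GAMMA_H**2 * _HBAR / _R_HH**3) ** 2


def tq_buildup_ratio(T: np.ndarray, eta: float, delta: float = 0.0) -> np.ndarray:
    """Cross-correlated-relaxation TQ/SQ build-up ratio at delay T.

    The default pluggable model: with build-up rate η and a small
    correction rate δ from external protons,

        I_TQ/I_SQ = 0.75 · η·tanh(√(η²+δ²)·T) / (√(η²+δ²) − δ·tanh(...))

    which reduces to ``0.75·tanh(ηT)`` when δ = 0 and to ``0.75·η·T`` at
    short delays.
    """
    T = np.asarray(T, dtype=float)
    root = math.hypot(eta, delta)
    if root == 0.0:
        return np.zeros_like(T)
    th = np.tanh(root * T)
    return 0.75 * eta * th / (root - delta * th)


def fit_s2tc(
    series: BuildupSeries,
    model: Callable[[np.ndarray, float, float], np.ndarray] = tq_buildup_ratio,
    eta_coeff: float = S2TC_ETA_COEFF,
) -> FitResult:
    """S²τc (s) from the TQ/SQ intensity-ratio build-up.

    Least-squares fit of the supplied build-up model's rate parameter η to
    the measured ratio curve; S²τc = η / eta_coeff.  A non-monotone ratio
    at short delays triggers a warning (build-up should start linearly).
    """
    if series.delays.size < 5:
        raise ValueError("need >= 5 build-up delays")
    ratio = series.I_TQ / series.I_SQ
    order = np.argsort(series.delays)
    r_sorted = ratio[order]
    if r_sorted.size >= 3 and r_sorted[1] < r_sorted[0] - 3 * np.std(r_sorted) * 0.1:
        warnings.warn("build-up ratio non-monotone at short delays")

    def f(T, eta, delta):
        return model(T, eta, delta)

    slope0 = max(r_sorted[0] / series.delays[order][0] / 0.75, 1.0)
    popt, pcov = curve_fit(
        f, series.delays, ratio, p0=[slope0, 0.0], maxfev=20000
    )
    eta = float(popt[0])
    eta_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
    return FitResult(
        value=eta / eta_coeff,
        stderr=eta_se / eta_coeff,
        params={"eta": eta, "delta": float(popt[1])},
    )
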