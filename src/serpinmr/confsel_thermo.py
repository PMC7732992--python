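"""Conformational-selection thermodynamics for the N ⇌ I ⇌ B scheme.

The ligand binds only the intermediate conformation I, so for each variant
X the intramolecular equilibrium constant

    K_X = p_I / p_N = (δ_X − δ_N) / (δ_B − δ_X)

is read off the observed population-averaged shift δ_X, and the observed
(macroscopic) dissociation constant is inflated by the fraction of unbound
protein that is not binding-competent:

    Kd_obs = (1 + K_X) / K_X · Kd

where Kd is the intrinsic affinity of the ligand for the pure intermediate.
In normalised shift coordinates the reference variant sits at F = 0 and the
bound state at F = 1, so δ_N maps to an offset φ_N (≤ 0 when the reference
itself samples some intermediate) and δ_X to the fitted collinear fraction
F_X.

``global_fit`` fits both relations jointly across variants by weighted
least squares over (φ_N, ln Kd, {ln K_X}), with Kd residuals on a log
scale because apparent affinities span orders of magnitude.  Populations,
free energies (R = 1.9872e-3 kcal/mol/K, T = 298 K, 1 M standard state)
and bootstrap uncertainties are derived from the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "VariantObservation",
    "VariantEstimate",
    "ConfSelFit",
    "equilibrium_from_shift",
    "apparent_kd",
    "global_fit",
    "exchange_bound",
    "R_KCAL",
    "T_STANDARD",
]

R_KCAL = 1.9872e-3  # kcal mol^-1 K^-1
T_STANDARD = 298.0  # K


@dataclass
class VariantObservation:
    """Per-variant inputs to the global fit.

    ``fraction`` is the collinear CSP extent F_X (reference variant 0 by
    construction, bound state 1). ``Kd_app`` in molar. Either observation
    may be absent (None).
    """

    variant: str
    fraction: float | None = None
    fraction_se: float = 0.02
    Kd_app: float | None = None
    Kd_app_se: float | None = None

    def __post_init__(self) -> None:
        if self.Kd_app is not None and self.Kd_app <= 0:
            raise ValueError(f"{self.variant}: Kd_app must be positive")
        if self.fraction is None and self.Kd_app is None:
            raise ValueError(f"{self.variant}: no observations")

    @property
    def sigma_ln_kd(self) -> float:
        """Log-scale Kd error; relative s.e. maps onto ln Kd (0 if noiseless)."""
        if self.Kd_app is None or self.Kd_app_se is None:
            return 0.0
        return self.Kd_app_se / self.Kd_app

    # Weights never vanish even for noiseless observations, so the
    # objective stays finite; the bootstrap uses the actual s.e. instead.
    @property
    def fraction_weight(self) -> float:
        return self.fraction_se if self.fraction_se > 0 else 0.02

    @property
    def kd_weight(self) -> float:
        s = self.sigma_ln_kd
        return s if s > 0 else 0.05


@dataclass
class VariantEstimate:
    """Fitted per-variant equilibrium and energetics."""

    variant: str
    K: float
    p_I: float
    p_N: float
    dG_NI: float  # kcal/mol, G(I) − G(N) = −RT ln K
    p_I_se: float = math.nan
    fraction_pred: float = math.nan
    Kd_app_pred: float | None = None


@dataclass
class ConfSelFit:
    """Global conformational-selection fit result."""

    phi_N: float
    Kd_intrinsic: float
    dG_bind: float  # RT ln Kd at 1 M standard state, kcal/mol
    variants: dict[str, VariantEstimate]
    cost: float
    phi_N_se: float = math.nan
    Kd_intrinsic_se: float = math.nan
    n_bootstrap: int = 0
    converged: bool = True


def equilibrium_from_shift(delta_X: float, delta_N: float, delta_B: float) -> float:
    """Equilibrium constant K = p_I/p_N from a population-averaged shift.

    Warns (rather than fails) when δ_X falls outside the [δ_N, δ_B]
    interval, which yields an unphysical negative K.
    """
    if delta_B == delta_X:
        raise ZeroDivisionError("delta_B == delta_X: fully shifted, K diverges")
    K = (delta_X - delta_N) / (delta_B - delta_X)
    lo, hi = min(delta_N, delta_B), max(delta_N, delta_B)
    if not (lo <= delta_X <= hi):
        warnings.warn(
            f"observed shift {delta_X} outside [{lo}, {hi}]: negative K = {K:.4g}"
        )
    return K


def apparent_kd(K: float, Kd_intrinsic: float) -> float:
    """Macroscopic dissociation constant (1 + K)/K · Kd."""
    if K <= 0:
        raise ValueError("K must be positive: no binding-competent population")
    if Kd_intrinsic <= 0:
        raise ValueError("intrinsic Kd must be positive")
    return (1.0 + K) / K * Kd_intrinsic


def fraction_from_K(K: float, phi_N: float) -> float:
    """Predicted collinear fraction for a variant with equilibrium K.

    Inverse of ``equilibrium_from_shift`` in normalised coordinates
    (δ_N → φ_N, δ_B → 1):  F = (φ_N + K) / (1 + K).
    """
    return (phi_N + K) / (1.0 + K)


def _pack_residuals(theta, obs, fit_phi, fit_lnkd, phi_fixed, lnkd_fixed):
    k = 0
    if fit_phi:
        phi_N = theta[k]
        k += 1
    else:
        phi_N = phi_fixed
    if fit_lnkd:
        ln_kd = theta[k]
        k += 1
    else:
        ln_kd = lnkd_fixed
    res = []
    for i, ob in enumerate(obs):
        K = math.exp(theta[k + i])
        if ob.fraction is not None:
            res.append((fraction_from_K(K, phi_N) - ob.fraction) / ob.fraction_weight)
        if ob.Kd_app is not None:
            pred = math.log((1.0 + K) / K) + ln_kd
            res.append((pred - math.log(ob.Kd_app)) / ob.kd_weight)
    return np.asarray(res)


def _solve(obs, x0, fit_phi, fit_lnkd, phi_fixed, lnkd_fixed):
    return least_squares(
        _pack_residuals,
        x0,
        args=(obs, fit_phi, fit_lnkd, phi_fixed, lnkd_fixed),
        method="lm" if len(x0) <= _n_residuals(obs) else "trf",
        max_nfev=5000,
    )


def _n_residuals(obs) -> int:
    return sum(
        (ob.fraction is not None) + (ob.Kd_app is not None) for ob in obs
    )


def _initial_guess(obs, fit_phi, fit_lnkd) -> np.ndarray:
    kds = [ob.Kd_app for ob in obs if ob.Kd_app is not None]
    x0 = []
    if fit_phi:
        x0.append(0.0)
    if fit_lnkd:
        x0.append(math.log(min(kds) * 0.5) if kds else math.log(1e-8))
    for ob in obs:
        if ob.fraction is not None and 0.001 < ob.fraction < 0.999:
            K0 = ob.fraction / (1.0 - ob.fraction)
        else:
            K0 = 0.05
        x0.append(math.log(max(K0, 1e-4)))
    return np.asarray(x0)


def global_fit(
    observations: list[VariantObservation],
    n_bootstrap: int = 1000,
    seed: int = 0,
    temperature_K: float = T_STANDARD,
    fix_phi_N: float | None = None,
) -> ConfSelFit:
    """Globally fit φ_N, intrinsic Kd and per-variant K to all observations.

    Minimises the weighted sum of squared residuals of the fraction
    relation and the log apparent-Kd relation over (φ_N, ln Kd, {ln K_X}).
    Uncertainties come from a parametric bootstrap: observations are
    resampled from Gaussian (fractions) / lognormal (Kd) error models and
    refitted; reported s.e. are bootstrap standard deviations. With zero
    observation noise the intervals collapse to zero width.

    ``fix_phi_N`` pins the native-state offset instead of fitting it, in
    which case a single variant suffices and the fit reduces to reading
    the population directly off the observed fraction. The intrinsic Kd is
    only fitted when at least one apparent-Kd observation exists.
    """
    fit_phi = fix_phi_N is None
    fit_lnkd = any(ob.Kd_app is not None for ob in observations)
    if fit_phi and len(observations) < 2:
        raise ValueError("need at least 2 variants to fit the native offset")
    if all(ob.fraction is None for ob in observations) and not fit_lnkd:
        raise ValueError("no usable observations")

    x0 = _initial_guess(observations, fit_phi, fit_lnkd)
    phi_fixed = 0.0 if fix_phi_N is None else fix_phi_N
    lnkd_fixed = math.log(1e-8)
    sol = _solve(observations, x0, fit_phi, fit_lnkd, phi_fixed, lnkd_fixed)
    if not sol.success:
        raise RuntimeError(f"global fit failed to converge: {sol.message}")
    k = 0
    if fit_phi:
        phi_N = float(sol.x[k])
        k += 1
    else:
        phi_N = phi_fixed
    if phi_N >= 1.0:
        raise RuntimeError(
            f"degenerate geometry: fitted native offset {phi_N:.3f} >= 1"
        )
    if fit_lnkd:
        kd = math.exp(sol.x[k])
        k += 1
    else:
        kd = math.nan
    RT = R_KCAL * temperature_K
    k_off = k

    variants: dict[str, VariantEstimate] = {}
    for i, ob in enumerate(observations):
        K = math.exp(sol.x[k_off + i])
        p_I = K / (1.0 + K)
        variants[ob.variant] = VariantEstimate(
            variant=ob.variant,
            K=K,
            p_I=p_I,
            p_N=1.0 - p_I,
            dG_NI=-RT * math.log(K),
            fraction_pred=fraction_from_K(K, phi_N),
            Kd_app_pred=(
                apparent_kd(K, kd) if fit_lnkd and ob.Kd_app is not None else None
            ),
        )

    fit = ConfSelFit(
        phi_N=phi_N,
        Kd_intrinsic=kd,
        dG_bind=RT * math.log(kd) if fit_lnkd else math.nan,
        variants=variants,
        cost=float(sol.cost),
    )

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot_phi, boot_lnkd = [], []
        boot_pI: dict[str, list[float]] = {ob.variant: [] for ob in observations}
        for _ in range(n_bootstrap):
            resampled = []
            for ob in observations:
                frac = ob.fraction
                if frac is not None and ob.fraction_se > 0:
                    frac = frac + rng.normal(0.0, ob.fraction_se)
                kd_app = ob.Kd_app
                if kd_app is not None and ob.sigma_ln_kd > 0:
                    kd_app = kd_app * math.exp(rng.normal(0.0, ob.sigma_ln_kd))
                resampled.append(
                    VariantObservation(
                        variant=ob.variant,
                        fraction=frac,
                        fraction_se=ob.fraction_se,
                        Kd_app=kd_app,
                        Kd_app_se=(
                            ob.sigma_ln_kd * kd_app
                            if kd_app is not None
                            else None
                        ),
                    )
                )
            try:
                bsol = _solve(
                    resampled, sol.x, fit_phi, fit_lnkd, phi_fixed, lnkd_fixed
                )
            except Exception:
                continue
            if not bsol.success:
                continue
            j = 0
            if fit_phi:
                boot_phi.append(bsol.x[j])
                j += 1
            if fit_lnkd:
                boot_lnkd.append(bsol.x[j])
                j += 1
            for i, ob in enumerate(observations):
                Kb = math.exp(bsol.x[j + i])
                boot_pI[ob.variant].append(Kb / (1.0 + Kb))
        if boot_phi and len(boot_phi) > 1:
            fit.phi_N_se = float(np.std(boot_phi, ddof=1))
        if boot_lnkd and len(boot_lnkd) > 1:
            fit.Kd_intrinsic_se = kd * float(np.std(boot_lnkd, ddof=1))
        for name, vals in boot_pI.items():
            if len(vals) > 1:
                variants[name].p_I_se = float(np.std(vals, ddof=1))
        fit.n_bootstrap = n_bootstrap
    return fit


def exchange_bound(dH: float, field_MHz: float) -> tuple[float, float]:
    """Exchange-lifetime upper bound from a 1H shift difference.

    Fast exchange requires the exchange rate to greatly exceed the angular
    frequency separation Δω = γB₀Δδ = 2π · field · Δδ (rad/s); the
    corresponding lifetime bound is τ < 1/Δω.

    Returns ``(delta_omega_rad_per_s, tau_upper_s)``.
    """
    if field_MHz <= 0:
        raise ValueError("field_MHz must be positive")
    delta_omega = 2.0 * math.pi * field_MHz * 1e6 * dH * 1e-6
    if delta_omega == 0.0:
        raise ValueError("zero shift difference: no exchange bound")
    delta_omega = abs(delta_omega)
    return delta_omega, 1.0 / delta_omega
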