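"""Collinear-CSP regression.

When a protein exchanges rapidly between a native (N) and an intermediate
(I) conformation, every resonance sits at the population-weighted average
of the two state shifts.  A variant that shifts the N⇌I equilibrium
therefore moves all of its resonances a *common fraction* of the way along
the vector joining the two endpoint spectra.  Plotting each variant shift
difference against the corresponding free→bound shift difference and
fitting a line through the origin measures that fraction directly.

1H and 13C differences enter as independent points, with 13C scaled by
0.25 to account for the gyromagnetic-ratio difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .csp import CSPRecord, CARBON_SCALE
from .peaklist_io import MethylSite

__all__ = ["CollinearFit", "build_regression_points", "fit_through_origin"]


@dataclass
class CollinearFit:
    """Slope of variant CSPs along the free→bound CSP axis."""

    fraction: float
    stderr: float
    n_points: int
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    included_sites: list[MethylSite] = field(default_factory=list, repr=False)


def build_regression_points(
    csp_variant: list[CSPRecord],
    csp_bound: list[CSPRecord],
    min_abs_x: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, list[MethylSite]]:
    """Assemble (x, y) pairs for the through-origin regression.

    For every site present and non-excluded in both tables, two points are
    emitted: the 1H pair ``(dH_bound, dH_variant)`` and the scaled 13C pair
    ``(0.25*dC_bound, 0.25*dC_variant)``. ``min_abs_x`` optionally drops
    points whose reference shift is noise-dominated (default keeps all).

    Returns ``(x, y, included_sites)``.
    """
    bvar = {r.site: r for r in csp_variant if not r.excluded}
    bbnd = {r.site: r for r in csp_bound if not r.excluded}
    shared = sorted(set(bvar) & set(bbnd))
    xs: list[float] = []
    ys: list[float] = []
    included = []
    for site in shared:
        rv, rb = bvar[site], bbnd[site]
        pts = [
            (rb.dH, rv.dH),
            (CARBON_SCALE * rb.dC, CARBON_SCALE * rv.dC),
        ]
        used = False
        for x, y in pts:
            if abs(x) >= min_abs_x:
                xs.append(x)
                ys.append(y)
                used = True
        if used:
            included.append(site)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared non-excluded sites, got {len(shared)}"
        )
    return np.asarray(xs), np.asarray(ys), included


def fit_through_origin(
    x: np.ndarray, y: np.ndarray, included_sites: list[MethylSite] | None = None
) -> CollinearFit:
    """Least-squares slope of ``y = f·x`` through the origin.

    ``f = Σxy / Σx²``;  ``stderr = sqrt(Σ(y − f·x)² / ((n−1)·Σx²))`` with
    n−1 degrees of freedom for the single fitted parameter.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("all x are zero: no collinearity direction to fit")
    f = float(x @ y) / sxx
    resid = y - f * x
    n = x.size
    stderr = math.sqrt(float(resid @ resid) / ((n - 1) * sxx))
    syy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else math.nan
    return CollinearFit(
        fraction=f,
        stderr=stderr,
        n_points=n,
        r_squared=r2,
        residuals=resid,
        included_sites=list(included_sites or []),
    )
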