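"""Chemical-shift-perturbation tables between two protein states.

The combined methyl CSP mixes the 1H and 13C shift differences with the
13C term scaled by 1/4 (the ratio of gyromagnetic ratios):

    dCH = sqrt(dH**2 + (dC / 4)**2)

Sites adjacent to a mutation or to the ligand binding pocket report direct
changes to their local chemical environment rather than the global
conformational equilibrium, so they can be flagged for exclusion from the
downstream collinearity regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaklist_io import MethylSite, PeakList, StructureModel

__all__ = [
    "CSPRecord",
    "combined_csp",
    "csp_table",
    "flag_local_sites",
    "detect_doubled_peaks",
    "records_to_frame",
    "DEFAULT_ADJACENCY_CUTOFF",
]

#: Default adjacency shell (Å) used to call a methyl "directly adjacent"
#: to a mutation site or the ligand pocket.
DEFAULT_ADJACENCY_CUTOFF = 8.0

#: 13C shift scaling relative to 1H in combined/weighted shift metrics.
CARBON_SCALE = 0.25


@dataclass
class CSPRecord:
    """Per-site shift difference between two states (state2 − state1)."""

    site: MethylSite
    dH: float
    dC: float
    dCH: float
    intensity_ratio: float = math.nan
    excluded: bool = False
    exclusion_reason: str = "none"  # near_mutation | near_ligand | untraced | none


def combined_csp(dH: float, dC: float) -> float:
    """Combined methyl CSP, ``sqrt(dH² + (dC/4)²)`` in ppm."""
    dH, dC = float(dH), float(dC)
    if not (math.isfinite(dH) and math.isfinite(dC)):
        raise ValueError("shift differences must be finite")
    return math.hypot(dH, CARBON_SCALE * dC)


def csp_table(
    list1: PeakList, list2: PeakList
) -> tuple[list[CSPRecord], list[MethylSite]]:
    """Compute per-site CSPs (list2 − list1) for sites assigned in both lists.

    Returns ``(records, untraced)`` where ``untraced`` holds sites assigned
    in exactly one list — resonances whose new location could not be traced.
    Intensity ratios are normalised for concentration and acquisition time:
    ``(I2/norm2) / (I1/norm1)`` with ``norm = concentration_uM * n_scans_norm``.
    """
    a1, a2 = list1.assigned, list2.assigned
    shared = sorted(set(a1) & set(a2))
    if not shared:
        raise ValueError(
            f"no shared assigned sites between states "
            f"{list1.state_label!r} and {list2.state_label!r}"
        )
    untraced = sorted(set(a1) ^ set(a2))

    norm1 = list1.concentration_uM * list1.n_scans_norm
    norm2 = list2.concentration_uM * list2.n_scans_norm
    records = []
    for site in shared:
        p1, p2 = a1[site], a2[site]
        dH = p2.delta_H - p1.delta_H
        dC = p2.delta_C - p1.delta_C
        if p1.intensity > 0 and norm1 > 0 and norm2 > 0:
            ratio = (p2.intensity / norm2) / (p1.intensity / norm1)
        else:
            ratio = math.nan
        records.append(
            CSPRecord(site=site, dH=dH, dC=dC, dCH=combined_csp(dH, dC),
                      intensity_ratio=ratio)
        )
    return records, untraced


def flag_local_sites(
    records: list[CSPRecord],
    structure: StructureModel,
    cutoff: float = DEFAULT_ADJACENCY_CUTOFF,
) -> list[CSPRecord]:
    """Mark records whose methyl lies within ``cutoff`` Å of a mutation Cα
    (reason ``near_mutation``) or any ligand atom (``near_ligand``).

    Mutation adjacency is tested first. Sites missing from the structure are
    flagged ``untraced`` with a warning. Flags already set are left alone;
    the operation is independent of record order.
    """
    out = []
    for rec in records:
        if rec.excluded:
            out.append(rec)
            continue
        if rec.site not in structure.methyl_coords:
            warnings.warn(f"site {rec.site.label} absent from structure")
            rec.excluded, rec.exclusion_reason = True, "untraced"
        elif structure.min_distance(rec.site, "mutation") <= cutoff:
            rec.excluded, rec.exclusion_reason = True, "near_mutation"
        elif structure.min_distance(rec.site, "ligand") <= cutoff:
            rec.excluded, rec.exclusion_reason = True, "near_ligand"
        out.append(rec)
    return out


def detect_doubled_peaks(
    peaklist: PeakList, tol_H: float = 0.01, tol_C: float = 0.04
) -> list[MethylSite]:
    """Find sites carrying two resolved peaks (e.g. glycoform doubling).

    A site is *doubled* when two picked peaks share its assignment and are
    separated by more than ``tol_H`` in 1H or ``tol_C`` in 13C; both peaks
    get ``doubled_flag`` set. Defaults are of the order of a linewidth.
    """
    by_site: dict[MethylSite, list] = {}
    for p in peaklist.peaks:
        if p.site is not None:
            by_site.setdefault(p.site, []).append(p)
    doubled = []
    for site, peaks in by_site.items():
        if len(peaks) < 2:
            continue
        for i in range(len(peaks)):
            for j in range(i + 1, len(peaks)):
                if (
                    abs(peaks[i].delta_H - peaks[j].delta_H) > tol_H
                    or abs(peaks[i].delta_C - peaks[j].delta_C) > tol_C
                ):
                    doubled.append(site)
                    for p in peaks:
                        p.doubled_flag = True
                    break
            else:
                continue
            break
    return sorted(doubled)


def records_to_frame(records: list[CSPRecord]) -> pd.DataFrame:
    """CSP records as a tidy DataFrame (one row per site)."""
    return pd.DataFrame(
        {
            "site": [r.site.label for r in records],
            "dH": [r.dH for r in records],
            "dC": [r.dC for r in records],
            "dCH": [r.dCH for r in records],
            "intensity_ratio": [r.intensity_ratio for r in records],
            "excluded": [r.excluded for r in records],
            "reason": [r.exclusion_reason for r in records],
        }
    )
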