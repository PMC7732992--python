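"""Structure-guided transfer of methyl assignments between spectra.

Assignments made on a fully assigned reference spectrum are carried onto
an unassigned target spectrum in three tiers of increasing permissiveness:

1. **unperturbed** — a reference peak has a unique mutual partner within a
   tight shift window; these anchor the mapping.
2. **tolerance** — remaining peaks are matched greedily, smallest combined
   shift distance first, inside the transfer window (≤0.05 ppm 1H and
   ≤0.1 ppm 13C).
3. **structural** — larger perturbations are accepted only with structural
   support: the site sits inside the adjacency shell of a declared
   mutation/ligand/glycosylation point, or its spatial neighbours are
   already seen to be perturbed; and for Ile/Leu/Val the partner methyl of
   the same residue must show a perturbation of comparable magnitude.

Stages 2–3 are iterated until the mapping is self-consistent, because the
structural evidence (perturbed neighbours, partner displacements) grows as
the mapping fills in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .csp import combined_csp
from .peaklist_io import (
    METHYL_IDS_BY_RESIDUE,
    MethylSite,
    PeakList,
    StructureModel,
)

__all__ = ["TransferParams", "TransferResult", "transfer_assignments", "apply_mapping"]


@dataclass(frozen=True)
class TransferParams:
    """Thresholds controlling the three matching tiers (all in ppm/Å)."""

    unperturbed_tol: tuple[float, float] = (0.005, 0.02)  # 1H, 13C
    tolerance_tol: tuple[float, float] = (0.05, 0.1)  # 1H, 13C
    stage3_max_csp: float = 0.6  # combined ppm; sanity cap on tier-3 moves
    adjacency_cutoff: float = 8.0  # Å, to mutation/ligand/glyco points
    neighbour_cutoff: float = 8.0  # Å, methyl-methyl neighbour shell
    neighbour_perturbed_min: float = 0.02  # combined ppm
    pair_factor: float = 3.0  # I/L/V partner-magnitude agreement
    pair_floor: float = 0.005  # combined ppm; avoids ratios on pure noise
    max_iter: int = 50


@dataclass
class TransferResult:
    """One-to-one mapping from reference methyl sites to target peaks."""

    mapping: dict[MethylSite, int]
    tier: dict[MethylSite, str]
    score: dict[MethylSite, float]  # combined shift-space distance, ppm
    untraced_sites: list[MethylSite]
    unassigned_targets: list[int]
    converged: bool = True
    n_iterations: int = 0


def _dist(ref_peak, tgt_peak) -> float:
    return combined_csp(
        tgt_peak.delta_H - ref_peak.delta_H, tgt_peak.delta_C - ref_peak.delta_C
    )


def _partner_site(site: MethylSite) -> MethylSite | None:
    mids = METHYL_IDS_BY_RESIDUE[site.residue_type]
    if len(mids) < 2:
        return None
    other = mids[0] if site.methyl_id == mids[1] else mids[1]
    return MethylSite(site.residue_number, other, site.residue_type)


def transfer_assignments(
    reference: PeakList,
    target: PeakList,
    structure: StructureModel | None = None,
    params: TransferParams = TransferParams(),
) -> TransferResult:
    """Map every reference site onto a target peak where the evidence allows.

    Requires a fully assigned reference. The structural tier is skipped
    when no structure is supplied. Ties in candidate distance are broken
    by lower residue number, then methyl label, making the result
    independent of input peak order.
    """
    ref_assigned = reference.assigned
    if any(p.site is None for p in reference.peaks):
        raise ValueError("reference peak list is not fully assigned")
    sites = sorted(ref_assigned)
    tgt_peaks = list(target.peaks)
    n_tgt = len(tgt_peaks)

    mapping: dict[MethylSite, int] = {}
    tier: dict[MethylSite, str] = {}
    score: dict[MethylSite, float] = {}

    # ---- stage 1: mutual unique matches within the tight window
    tolH, tolC = params.unperturbed_tol
    for site in sites:
        rp = ref_assigned[site]
        close = [
            j
            for j, tp in enumerate(tgt_peaks)
            if abs(tp.delta_H - rp.delta_H) <= tolH
            and abs(tp.delta_C - rp.delta_C) <= tolC
        ]
        if len(close) != 1:
            continue
        j = close[0]
        others = [
            s
            for s in sites
            if s != site
            and abs(tgt_peaks[j].delta_H - ref_assigned[s].delta_H) <= tolH
            and abs(tgt_peaks[j].delta_C - ref_assigned[s].delta_C) <= tolC
        ]
        if others or j in mapping.values():
            continue
        mapping[site] = j
        tier[site] = "unperturbed"
        score[site] = _dist(ref_assigned[site], tgt_peaks[j])

    # ---- stages 2-3, iterated to self-consistency
    tol2H, tol2C = params.tolerance_tol
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        before = dict(mapping)
        free_sites = [s for s in sites if s not in mapping]
        used = set(mapping.values())
        free_tgts = [j for j in range(n_tgt) if j not in used]

        # stage 2: greedy smallest-combined-distance inside the window
        cands = []
        for s in free_sites:
            rp = ref_assigned[s]
            for j in free_tgts:
                tp = tgt_peaks[j]
                if (
                    abs(tp.delta_H - rp.delta_H) <= tol2H
                    and abs(tp.delta_C - rp.delta_C) <= tol2C
                ):
                    cands.append((_dist(rp, tp), s.residue_number, s.methyl_id, s, j))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        taken_t: set[int] = set()
        for d, _, _, s, j in cands:
            if s in mapping or j in taken_t:
                continue
            mapping[s] = j
            tier[s] = "tolerance"
            score[s] = d
            taken_t.add(j)

        # stage 3: structural acceptance of larger moves
        if structure is not None:
            free_sites = [s for s in sites if s not in mapping]
            used = set(mapping.values())
            free_tgts = [j for j in range(n_tgt) if j not in used]
            cands = []
            for s in free_sites:
                rp = ref_assigned[s]
                for j in free_tgts:
                    d = _dist(rp, tgt_peaks[j])
                    if d <= params.stage3_max_csp:
                        cands.append((d, s.residue_number, s.methyl_id, s, j))
            cands.sort(key=lambda c: (c[0], c[1], c[2]))
            taken_t = set()
            for d, _, _, s, j in cands:
                if s in mapping or j in taken_t:
                    continue
                if not _structural_support(
                    s, structure, mapping, score, params
                ):
                    continue
                if not _partner_consistent(
                    s, d, ref_assigned, tgt_peaks, mapping, score, params
                ):
                    continue
                mapping[s] = j
                tier[s] = "structural"
                score[s] = d
                taken_t.add(j)

        if mapping == before:
            converged = True
            break

    if not converged:
        warnings.warn("assignment transfer did not converge; best mapping returned")

    untraced = [s for s in sites if s not in mapping]
    unassigned = sorted(set(range(n_tgt)) - set(mapping.values()))
    return TransferResult(
        mapping=mapping,
        tier=tier,
        score=score,
        untraced_sites=untraced,
        unassigned_targets=unassigned,
        converged=converged,
        n_iterations=n_iter,
    )


def _structural_support(site, structure, mapping, score, params) -> bool:
    """Tier-3 condition (a): near a declared perturbation source, or the
    structural neighbourhood already carries perturbations."""
    if site not in structure.methyl_coords:
        return False
    for kind in ("mutation", "ligand", "glyco"):
        if structure.min_distance(site, kind) <= params.adjacency_cutoff:
            return True
    for nb in structure.neighbours_within(site, params.neighbour_cutoff):
        if nb in mapping and score[nb] >= params.neighbour_perturbed_min:
            return True
    return False


def _partner_consistent(
    site, d, ref_assigned, tgt_peaks, mapping, score, params
) -> bool:
    """Tier-3 condition (b): for I/L/V, the partner methyl of the residue
    must show a perturbation of comparable magnitude (within pair_factor).

    A partner already mapped contributes its realised displacement; an
    unmapped partner contributes its best-case (minimum) displacement to
    any remaining target peak.
    """
    partner = _partner_site(site)
    if partner is None:
        return True  # Met/Ala have no partner constraint
    if partner not in ref_assigned:
        return True
    if partner in mapping:
        p_disp = score[partner]
    else:
        pp = ref_assigned[partner]
        used = set(mapping.values())
        dists = [
            _dist(pp, tp) for j, tp in enumerate(tgt_peaks) if j not in used
        ]
        if not dists:
            return False
        p_disp = min(dists)
    lo = max(min(d, p_disp), params.pair_floor)
    hi = max(max(d, p_disp), params.pair_floor)
    return hi / lo <= params.pair_factor


def apply_mapping(target: PeakList, result: TransferResult) -> PeakList:
    """Return a copy of the target list with transferred assignments set."""
    inverse = {j: s for s, j in result.mapping.items()}
    new_peaks = [
        replace(p, site=inverse.get(j, None)) for j, p in enumerate(target.peaks)
    ]
    return replace(target, peaks=new_peaks)
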