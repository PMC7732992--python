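"""Ground-truth scenario generation for pipeline validation.

The generative model is the same two-state fast-exchange picture the
analysis assumes: every methyl site has a native shift δ_N and an
intermediate shift δ_I, each variant X populates the intermediate with a
fixed fraction p_I(X), and the observed position is the population-weighted
average (1−p)δ_N + p·δ_I plus Gaussian noise.  The ligand-bound state sits
at δ_I.  A declared subset of sites near synthetic mutation/ligand points
additionally receives non-collinear local offsets, emulating the direct
chemical perturbations that the structural exclusion step must remove.

Matching apparent Kd values are produced from the *same* thermodynamic
parameters through the conformational-selection relation, so the full
pipeline (CSP → regression → global fit) can be checked for end-to-end
parameter recovery.

Default populations encode the study conditions: a wild-type-like
reference sampling ~2% intermediate, a strongly shifted Z-like variant at
27% and an S-like variant indistinguishable from the reference (relative
collinear extent 0.4%).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ancillary_assays import GAMMA_H, S2TC_ETA_COEFF, tq_buildup_ratio
from .confsel_thermo import apparent_kd
from .peaklist_io import (
    METHYL_IDS_BY_RESIDUE,
    MethylPeak,
    MethylSite,
    PeakList,
    StructureModel,
    write_peaklist,
)

__all__ = [
    "SyntheticScenario",
    "generate_scenario",
    "render_peaklists",
    "render_assays",
    "write_scenario_dir",
    "DEFAULT_POPULATIONS",
]

# Reference (M-like) intermediate population chosen so the native-state
# offset on the collinear axis is phi_N = -K_M = -0.02; Z-like at the 27%
# intermediate population; S-like at a 0.4% relative collinear extent.
_K_M = 0.02
_P_M = _K_M / (1.0 + _K_M)
DEFAULT_POPULATIONS: dict[str, float] = {
    "M": _P_M,
    "Z": 0.27,
    "S": _P_M + 0.004 * (1.0 - _P_M),
}

_RESIDUE_TYPES = ("I", "L", "V", "M", "A")
# 13C methyl shift ranges (ppm) per residue type, spanning the dispersion
# typical of a folded protein's methyl region (BMRB-scale statistics).
_C_RANGES = {
    "I": (8.0, 19.0),
    "L": (20.0, 27.0),
    "V": (18.0, 24.0),
    "M": (13.0, 19.0),
    "A": (15.0, 23.0),
}
# 1H methyl range; folded-protein ring-current shifts extend below 0 ppm.
_H_RANGE = (-0.3, 1.5)


@dataclass
class SyntheticScenario:
    """A fully specified ground-truth dataset."""

    sites: list[MethylSite]
    delta_N: np.ndarray  # (n_sites, 2): 1H, 13C ppm
    delta_I: np.ndarray  # (n_sites, 2)
    p_I_per_variant: dict[str, float]
    noise: tuple[float, float]  # (sigma_H, sigma_C) ppm
    local_offsets: dict[int, np.ndarray]  # site index -> extra (dH, dC)
    local_kind: dict[int, str]  # site index -> "mutation" | "ligand"
    structure: StructureModel
    Kd_intrinsic: float
    seed: int
    si_per_variant: dict[str, float] = field(
        default_factory=lambda: {"M": 1.0, "Z": 1.5, "S": 1.0}
    )
    diffusion_D: float = 6.0e-11  # m^2/s
    s2tc: float = 1.5e-8  # s

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def variant_fraction(self, variant: str, reference: str = "M") -> float:
        """Ground-truth collinear extent of ``variant`` relative to the
        reference, F = (p_X − p_ref)/(1 − p_ref)."""
        p_ref = self.p_I_per_variant[reference]
        p_x = self.p_I_per_variant[variant]
        return (p_x - p_ref) / (1.0 - p_ref)

    @property
    def phi_N(self) -> float:
        """Native-state offset on the collinear axis, −p_ref/(1−p_ref)."""
        p_ref = self.p_I_per_variant["M"]
        return -p_ref / (1.0 - p_ref)

    def K(self, variant: str) -> float:
        p = self.p_I_per_variant[variant]
        return p / (1.0 - p)

    def Kd_app(self, variant: str) -> float:
        return apparent_kd(self.K(variant), self.Kd_intrinsic)


def _make_sites(rng: np.random.Generator, n_sites: int) -> list[MethylSite]:
    """Draw residues until n_sites methyls exist; I/L/V contribute pairs."""
    sites: list[MethylSite] = []
    resnum = 10
    while len(sites) < n_sites:
        rtype = _RESIDUE_TYPES[rng.integers(len(_RESIDUE_TYPES))]
        for mid in METHYL_IDS_BY_RESIDUE[rtype]:
            if len(sites) < n_sites:
                sites.append(MethylSite(resnum, mid, rtype))
        resnum += 1
    return sites


def generate_scenario(
    n_sites: int = 150,
    p_I_per_variant: dict[str, float] | None = None,
    noise: tuple[float, float] = (0.005, 0.02),
    n_local_sites: int = 10,
    Kd_intrinsic: float = 15e-9,
    seed: int = 0,
    adjacency_cutoff: float = 8.0,
) -> SyntheticScenario:
    """Generate a reproducible ground-truth scenario.

    Per-site intermediate perturbation vectors δ_I − δ_N have random
    orientation in (1H, 13C/4) shift space with combined magnitudes drawn
    log-uniformly in [0.01, 0.3] ppm, matching the scale of observed
    free→bound CSPs.  ``n_local_sites`` sites are placed inside the
    adjacency shell of a synthetic mutation point or ligand atom and get
    extra, deliberately non-collinear offsets; all other sites are kept
    well outside both shells.
    """
    pops = dict(p_I_per_variant or DEFAULT_POPULATIONS)
    for v, p in pops.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"population for {v!r} outside [0, 1]: {p}")
    if not 0 <= n_local_sites < n_sites:
        raise ValueError("n_local_sites must be < n_sites")

    rng = np.random.default_rng(seed)
    sites = _make_sites(rng, n_sites)

    dN = np.column_stack(
        [
            rng.uniform(*_H_RANGE, size=n_sites),
            np.array(
                [rng.uniform(*_C_RANGES[s.residue_type]) for s in sites]
            ),
        ]
    )
    # perturbation in (H, C/4) space; store as (dH, dC)
    mag = np.exp(rng.uniform(math.log(0.01), math.log(0.3), size=n_sites))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_sites)
    dvec = np.column_stack([mag * np.cos(theta), 4.0 * mag * np.sin(theta)])
    dI = dN + dvec

    # local-perturbation sites: extra offsets orthogonal-ish to the global
    # axis so they are non-collinear and must be excluded structurally
    local_idx = rng.choice(n_sites, size=n_local_sites, replace=False)
    local_offsets: dict[int, np.ndarray] = {}
    local_kind: dict[int, str] = {}
    for j, idx in enumerate(sorted(local_idx)):
        m = rng.uniform(0.1, 0.3)
        ang = theta[idx] + math.pi / 2.0 + rng.normal(0.0, 0.3)
        local_offsets[int(idx)] = np.array(
            [m * math.cos(ang), 4.0 * m * math.sin(ang)]
        )
        local_kind[int(idx)] = "mutation" if j % 2 == 0 else "ligand"

    # toy geometry: mutation Calpha at origin, ligand centroid far away;
    # residues (not methyls) get coordinates so methyl pairs stay together
    mutation_point = np.zeros(3)
    ligand_point = np.array([60.0, 0.0, 0.0])
    coords: dict[MethylSite, np.ndarray] = {}
    by_res: dict[int, list[int]] = {}
    for i, s in enumerate(sites):
        by_res.setdefault(s.residue_number, []).append(i)
    for resnum, idxs in by_res.items():
        kinds = {local_kind.get(i) for i in idxs} - {None}
        if "mutation" in kinds:
            centre = mutation_point + _random_shell(rng, 3.0, adjacency_cutoff - 2.0)
        elif "ligand" in kinds:
            centre = ligand_point + _random_shell(rng, 3.0, adjacency_cutoff - 2.0)
        else:
            # keep bystander sites outside both adjacency shells
            while True:
                centre = rng.uniform([-40.0, -40.0, -40.0], [40.0, 40.0, 40.0])
                centre[0] += 30.0
                if (
                    np.linalg.norm(centre - mutation_point) > adjacency_cutoff + 4.0
                    and np.linalg.norm(centre - ligand_point) > adjacency_cutoff + 4.0
                ):
                    break
        if kinds:
            point = mutation_point if "mutation" in kinds else ligand_point
            for i in idxs:
                # keep every locally perturbed methyl inside the shell
                while True:
                    xyz = centre + rng.normal(0.0, 0.8, size=3)
                    if np.linalg.norm(xyz - point) <= adjacency_cutoff - 0.5:
                        break
                coords[sites[i]] = xyz
        else:
            for i in idxs:
                coords[sites[i]] = centre + rng.normal(0.0, 0.8, size=3)
        # a residue is local if any of its methyls is; propagate the offsets
        if kinds:
            kind = "mutation" if "mutation" in kinds else "ligand"
            for i in idxs:
                if i not in local_offsets:
                    m = rng.uniform(0.1, 0.3)
                    ang = theta[i] + math.pi / 2.0 + rng.normal(0.0, 0.3)
                    local_offsets[i] = np.array(
                        [m * math.cos(ang), 4.0 * m * math.sin(ang)]
                    )
                local_kind[i] = kind

    structure = StructureModel(
        methyl_coords=coords,
        mutation_points=[("mut", mutation_point)],
        ligand_atoms=[ligand_point],
    )
    return SyntheticScenario(
        sites=sites,
        delta_N=dN,
        delta_I=dI,
        p_I_per_variant=pops,
        noise=noise,
        local_offsets=local_offsets,
        local_kind=local_kind,
        structure=structure,
        Kd_intrinsic=Kd_intrinsic,
        seed=seed,
    )


def _random_shell(rng, r_min: float, r_max: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * rng.uniform(r_min, r_max)


def render_peaklists(
    scenario: SyntheticScenario,
    bound_label: str = "M+716",
    with_noise: bool = True,
    seed_offset: int = 1,
) -> dict[str, PeakList]:
    """Render assigned peak lists for every variant plus the bound state.

    Observed shifts follow the fast-exchange rule δ = (1−p)δ_N + p·δ_I per
    site per variant; the bound state sits at δ_I.  Local offsets apply to
    mutation-adjacent sites in variant states and to ligand-adjacent sites
    in the bound state.  Noise is Gaussian with the scenario's (σ_H, σ_C),
    drawn from a stream derived from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed + seed_offset)
    sH, sC = scenario.noise if with_noise else (0.0, 0.0)
    lists: dict[str, PeakList] = {}

    def emit(label: str, positions: np.ndarray) -> PeakList:
        noisy = positions + np.column_stack(
            [
                rng.normal(0.0, sH, size=scenario.n_sites) if sH > 0 else np.zeros(scenario.n_sites),
                rng.normal(0.0, sC, size=scenario.n_sites) if sC > 0 else np.zeros(scenario.n_sites),
            ]
        )
        peaks = [
            MethylPeak(
                delta_H=float(noisy[i, 0]),
                delta_C=float(noisy[i, 1]),
                intensity=1.0,
                site=site,
            )
            for i, site in enumerate(scenario.sites)
        ]
        return PeakList(state_label=label, peaks=peaks)

    for variant, p in scenario.p_I_per_variant.items():
        pos = (1.0 - p) * scenario.delta_N + p * scenario.delta_I
        if variant != "M":
            for idx, off in scenario.local_offsets.items():
                if scenario.local_kind[idx] == "mutation":
                    pos[idx] = pos[idx] + off
        lists[variant] = emit(variant, pos)

    bound = scenario.delta_I.copy()
    for idx, off in scenario.local_offsets.items():
        if scenario.local_kind[idx] == "ligand":
            bound[idx] = bound[idx] + off
    lists[bound_label] = emit(bound_label, bound)
    return lists


def render_assays(
    scenario: SyntheticScenario,
    noise_frac: float = 0.0,
    seed_offset: int = 2,
) -> dict:
    """Render SI, FP-titration, diffusion and TQ-build-up fixture curves.

    Apparent Kd values come from the conformational-selection relation
    applied to the scenario's own populations, so the FP midpoints are
    thermodynamically consistent with the peak lists.  ``noise_frac`` adds
    proportional Gaussian noise to every rendered signal.
    """
    rng = np.random.default_rng(scenario.seed + seed_offset)

    def jitter(y: np.ndarray) -> np.ndarray:
        if noise_frac <= 0:
            return y
        return y * (1.0 + rng.normal(0.0, noise_frac, size=y.shape))

    out: dict = {"si": {}, "fp": {}, "diffusion": None, "buildup": None}

    ratios = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.25])
    for variant, si in scenario.si_per_variant.items():
        act = np.clip(1.0 - ratios / si, 0.0, None)
        out["si"][variant] = {"ratios": ratios, "activities": jitter(act)}

    probe = 10e-9
    for variant in scenario.p_I_per_variant:
        kd_app = scenario.Kd_app(variant)
        top = max(100e-6, kd_app * 50)
        conc = top / (2.0 ** np.arange(12))
        from .ancillary_assays import quadratic_bound_fraction

        fb = quadratic_bound_fraction(conc, probe, kd_app)
        signal = 0.05 + (0.30 - 0.05) * fb
        out["fp"][variant] = {
            "concentrations": conc,
            "signals": jitter(signal),
            "probe_conc": probe,
            "Kd_app_true": kd_app,
        }

    g = np.linspace(0.02, 0.98, 24) * 55.57
    delta, Delta = 4e-3, 100e-3
    b = GAMMA_H**2 * (g * 1e-2) ** 2 * delta**2 * (Delta - delta / 3.0)
    out["diffusion"] = {
        "gradients_G_per_cm": g,
        "signals": jitter(np.exp(-scenario.diffusion_D * b)),
        "delta_enc": delta,
        "Delta_diff": Delta,
        "D_true": scenario.diffusion_D,
    }

    delays = np.array([1.1, 3.0, 6.0, 10.0, 15.0, 25.0, 40.0]) * 1e-3
    eta = scenario.s2tc * S2TC_ETA_COEFF
    ratio = tq_buildup_ratio(delays, eta)
    out["buildup"] = {
        "delays": delays,
        "I_TQ": jitter(ratio),
        "I_SQ": np.ones_like(delays),
        "s2tc_true": scenario.s2tc,
    }
    return out


def _write_toy_pdb(scenario: SyntheticScenario, path: Path) -> None:
    """Write the scenario geometry as a minimal PDB file.

    Each methyl carbon appears under its catalogued atom name, each
    residue gets a Cα at the residue centroid, and the ligand is a HETATM
    residue named LIG. A mutation-point residue 999 carries only a Cα.
    """
    from .peaklist_io import METHYL_ATOM_NAMES

    one_to_three = {"I": "ILE", "L": "LEU", "V": "VAL", "M": "MET", "A": "ALA"}
    lines = []
    serial = 1

    def atom_line(serial, name, resname, resnum, xyz, het=False):
        record = "HETATM" if het else "ATOM  "
        return (
            f"{record}{serial:5d} {name:<4s}{resname:>4s} A{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )

    by_res: dict[int, list[MethylSite]] = {}
    for s in scenario.sites:
        by_res.setdefault(s.residue_number, []).append(s)
    for resnum in sorted(by_res):
        sites = by_res[resnum]
        resname = one_to_three[sites[0].residue_type]
        centroid = np.mean(
            [scenario.structure.methyl_coords[s] for s in sites], axis=0
        )
        lines.append(atom_line(serial, "CA", resname, resnum, centroid))
        serial += 1
        for s in sites:
            aname = METHYL_ATOM_NAMES[(s.residue_type, s.methyl_id)]
            lines.append(
                atom_line(
                    serial, aname, resname, resnum,
                    scenario.structure.methyl_coords[s],
                )
            )
            serial += 1
    for label, xyz in scenario.structure.mutation_points:
        lines.append(atom_line(serial, "CA", "GLY", 999, xyz))
        serial += 1
    for xyz in scenario.structure.ligand_atoms:
        lines.append(atom_line(serial, "C1", "LIG", 1000, xyz, het=True))
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_scenario_dir(
    scenario: SyntheticScenario,
    out_dir: str | Path,
    noise_frac_assays: float = 0.0,
) -> Path:
    """Materialise a scenario as files: Sparky lists, toy PDB, assay CSVs
    and a ground-truth JSON."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lists = render_peaklists(scenario)
    for label, pl in lists.items():
        safe = label.replace("+", "_")
        write_peaklist(pl, out / f"{safe}.list", dialect="sparky")
    _write_toy_pdb(scenario, out / "structure.pdb")
    assays = render_assays(scenario, noise_frac=noise_frac_assays)
    for variant, d in assays["si"].items():
        pd.DataFrame(
            {"ratio": d["ratios"], "activity": d["activities"]}
        ).to_csv(out / f"si_{variant}.csv", index=False)
    for variant, d in assays["fp"].items():
        pd.DataFrame(
            {"concentration_M": d["concentrations"], "signal": d["signals"]}
        ).to_csv(out / f"fp_{variant}.csv", index=False)
    d = assays["diffusion"]
    pd.DataFrame(
        {"gradient_G_per_cm": d["gradients_G_per_cm"], "signal": d["signals"]}
    ).to_csv(out / "diffusion.csv", index=False)
    d = assays["buildup"]
    pd.DataFrame(
        {"delay_s": d["delays"], "I_TQ": d["I_TQ"], "I_SQ": d["I_SQ"]}
    ).to_csv(out / "buildup.csv", index=False)

    truth = {
        "seed": scenario.seed,
        "n_sites": scenario.n_sites,
        "noise": list(scenario.noise),
        "p_I_per_variant": scenario.p_I_per_variant,
        "phi_N": scenario.phi_N,
        "Kd_intrinsic": scenario.Kd_intrinsic,
        "fractions": {
            v: scenario.variant_fraction(v)
            for v in scenario.p_I_per_variant
            if v != "M"
        },
        "Kd_app": {v: scenario.Kd_app(v) for v in scenario.p_I_per_variant},
        "local_sites": {
            scenario.sites[i].label: kind
            for i, kind in sorted(scenario.local_kind.items())
        },
        "si_per_variant": scenario.si_per_variant,
        "diffusion_D": scenario.diffusion_D,
        "s2tc": scenario.s2tc,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out
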