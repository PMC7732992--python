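"""Peak-list, chemical-shift-table and coordinate I/O.

Supported dialects:

* **sparky** — whitespace-delimited ``assignment  w1(1H ppm)  w2(13C ppm)
  height`` rows, the export format of Sparky-family assignment programs.
* **nmrstar** — the ``Atom_chem_shift`` loop of an NMR-STAR v3 file, the
  deposition format of the BMRB.  Methyl 1H/13C shift pairs are re-assembled
  from per-atom rows.
* **csv** — a plain table with ``assignment, delta_H, delta_C, intensity``
  columns.

Coordinates are read from PDB files via Bio.PDB; only the first MODEL and
altloc '' / 'A' are considered, so the geometry is single-conformer and
deterministic.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylSite",
    "MethylPeak",
    "PeakList",
    "StructureModel",
    "PeakListError",
    "read_peaklist",
    "write_peaklist",
    "read_structure",
    "write_results_table",
    "METHYL_IDS_BY_RESIDUE",
    "METHYL_ATOM_NAMES",
]


class PeakListError(ValueError):
    """Malformed peak-list or structure input."""


#: Methyl groups observable per residue type in ILVMA-methyl spectra.
METHYL_IDS_BY_RESIDUE: Mapping[str, tuple[str, ...]] = {
    "I": ("d1", "g2"),
    "L": ("d1", "d2"),
    "V": ("g1", "g2"),
    "M": ("e",),
    "A": ("b",),
}

#: PDB carbon atom name for each (residue type, methyl id).
METHYL_ATOM_NAMES: Mapping[tuple[str, str], str] = {
    ("I", "d1"): "CD1",
    ("I", "g2"): "CG2",
    ("L", "d1"): "CD1",
    ("L", "d2"): "CD2",
    ("V", "g1"): "CG1",
    ("V", "g2"): "CG2",
    ("M", "e"): "CE",
    ("A", "b"): "CB",
}

_THREE_TO_ONE = {"ILE": "I", "LEU": "L", "VAL": "V", "MET": "M", "ALA": "A"}

_ASSIGNMENT_RE = re.compile(r"^([ILVMA])(\d+)(d1|d2|g1|g2|e|b)$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class MethylSite:
    """One methyl group, identified by residue number and methyl label."""

    residue_number: int
    methyl_id: str
    residue_type: str

    def __post_init__(self) -> None:
        allowed = METHYL_IDS_BY_RESIDUE.get(self.residue_type)
        if allowed is None:
            raise PeakListError(
                f"unknown residue type {self.residue_type!r}; expected one of ILVMA"
            )
        if self.methyl_id not in allowed:
            raise PeakListError(
                f"methyl id {self.methyl_id!r} not allowed for residue type "
                f"{self.residue_type!r} (allowed: {allowed})"
            )

    @property
    def label(self) -> str:
        """Sparky-style assignment string, e.g. ``I375d1``."""
        return f"{self.residue_type}{self.residue_number}{self.methyl_id}"

    @classmethod
    def from_label(cls, label: str) -> "MethylSite":
        m = _ASSIGNMENT_RE.match(label.strip())
        if m is None:
            raise PeakListError(f"cannot parse assignment string {label!r}")
        rtype, num, mid = m.group(1).upper(), int(m.group(2)), m.group(3).lower()
        return cls(residue_number=num, methyl_id=mid, residue_type=rtype)


@dataclass
class MethylPeak:
    """A single 2D methyl resonance (1H, 13C position and intensity)."""

    delta_H: float
    delta_C: float
    intensity: float = 0.0
    site: MethylSite | None = None
    doubled_flag: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_H) and math.isfinite(self.delta_C)):
            raise PeakListError("peak position must be finite")
        if self.intensity < 0:
            raise PeakListError("peak intensity must be >= 0")
        if not (-2.0 <= self.delta_H <= 3.0) or not (5.0 <= self.delta_C <= 30.0):
            warnings.warn(
                f"peak at ({self.delta_H:.3f}, {self.delta_C:.3f}) ppm lies "
                "outside typical methyl ranges",
                stacklevel=2,
            )


@dataclass
class PeakList:
    """A per-state collection of methyl peaks with acquisition metadata.

    ``n_scans_norm`` carries an acquisition-time normalisation factor
    (e.g. number of scans); intensity comparisons between states divide by
    ``concentration_uM * n_scans_norm`` so that contour/intensity ratios are
    normalised for concentration and acquisition time.
    """

    state_label: str
    peaks: list[MethylPeak] = field(default_factory=list)
    field_MHz: float = 900.0
    temperature_K: float = 298.0
    concentration_uM: float = 400.0
    n_scans_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.field_MHz <= 0:
            raise PeakListError("field_MHz must be positive")
        self._check_unique_sites()

    def _check_unique_sites(self) -> None:
        # duplicates are tolerated (doubled peaks, e.g. glycoform splitting)
        # but warned about unless already flagged as doubled
        seen: set[MethylSite] = set()
        for p in self.peaks:
            if p.site is None:
                continue
            if p.site in seen and not p.doubled_flag:
                warnings.warn(
                    f"duplicate assignment {p.site.label} in state "
                    f"{self.state_label}; keeping both (doubled peak?)"
                )
            seen.add(p.site)

    @property
    def assigned(self) -> dict[MethylSite, MethylPeak]:
        """Mapping of site -> peak for assigned, non-doubled entries."""
        out: dict[MethylSite, MethylPeak] = {}
        for p in self.peaks:
            if p.site is not None and p.site not in out:
                out[p.site] = p
        return out

    def sorted_by_site(self) -> "PeakList":
        assigned = [p for p in self.peaks if p.site is not None]
        unassigned = [p for p in self.peaks if p.site is None]
        assigned.sort(key=lambda p: p.site)  # type: ignore[arg-type]
        unassigned.sort(key=lambda p: (p.delta_H, p.delta_C))
        return replace(self, peaks=assigned + unassigned)


@dataclass
class StructureModel:
    """Methyl-site coordinates plus mutation/ligand/glycan reference points.

    Coordinates are in Å; adjacency queries use plain Euclidean distance
    between heavy atoms.
    """

    methyl_coords: dict[MethylSite, np.ndarray]
    mutation_points: list[tuple[str, np.ndarray]] = field(default_factory=list)
    ligand_atoms: list[np.ndarray] = field(default_factory=list)
    glycosite_points: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for site, xyz in self.methyl_coords.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise PeakListError(f"bad coordinates for {site.label}")
            self.methyl_coords[site] = arr

    def reference_points(self, kinds: Sequence[str] = ("mutation", "ligand", "glyco")):
        """Yield (kind, xyz) over the selected reference point categories."""
        if "mutation" in kinds:
            for _, xyz in self.mutation_points:
                yield "mutation", xyz
        if "ligand" in kinds:
            for xyz in self.ligand_atoms:
                yield "ligand", xyz
        if "glyco" in kinds:
            for _, xyz in self.glycosite_points:
                yield "glyco", xyz

    def min_distance(self, site: MethylSite, kind: str) -> float:
        """Minimum distance (Å) from a methyl carbon to a point category."""
        xyz = self.methyl_coords.get(site)
        if xyz is None:
            raise KeyError(site)
        dists = [
            float(np.linalg.norm(xyz - p)) for k, p in self.reference_points((kind,))
        ]
        return min(dists) if dists else math.inf

    def neighbours_within(self, site: MethylSite, cutoff: float) -> list[MethylSite]:
        """Other methyl sites within ``cutoff`` Å of ``site``."""
        xyz = self.methyl_coords.get(site)
        if xyz is None:
            raise KeyError(site)
        out = []
        for other, oxyz in self.methyl_coords.items():
            if other == site:
                continue
            if float(np.linalg.norm(xyz - oxyz)) <= cutoff:
                out.append(other)
        return sorted(out)


# ---------------------------------------------------------------------------
# peak list readers / writers


def _parse_assignment(token: str) -> MethylSite | None:
    if token in {"?", "?-?", "-", ""}:
        return None
    try:
        return MethylSite.from_label(token)
    except PeakListError:
        warnings.warn(f"unparseable assignment {token!r}; peak kept unassigned")
        return None


def _read_sparky(path: Path) -> list[MethylPeak]:
    peaks: list[MethylPeak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if toks[0].lower() in {"assignment", "assign"}:  # header row
                continue
            if len(toks) < 3:
                raise PeakListError(f"{path}:{lineno}: expected >=3 columns")
            try:
                dH, dC = float(toks[1]), float(toks[2])
                inten = float(toks[3]) if len(toks) > 3 else 0.0
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: non-numeric field") from exc
            peaks.append(
                MethylPeak(
                    delta_H=dH,
                    delta_C=dC,
                    intensity=inten,
                    site=_parse_assignment(toks[0]),
                )
            )
    return peaks


def _read_csv(path: Path) -> list[MethylPeak]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"assignment", "delta_H", "delta_C"}
    if not required.issubset(df.columns):
        raise PeakListError(
            f"{path}: csv dialect needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    peaks = []
    for _, row in df.iterrows():
        token = "" if pd.isna(row["assignment"]) else str(row["assignment"])
        peaks.append(
            MethylPeak(
                delta_H=float(row["delta_H"]),
                delta_C=float(row["delta_C"]),
                intensity=float(row.get("intensity", 0.0) or 0.0),
                site=_parse_assignment(token),
            )
        )
    return peaks


# Atom name -> methyl id, used when re-assembling NMR-STAR per-atom rows.
_STAR_ATOM_TO_METHYL = {
    ("ILE", "CD1"): "d1", ("ILE", "HD1"): "d1", ("ILE", "HD11"): "d1",
    ("ILE", "CG2"): "g2", ("ILE", "HG2"): "g2", ("ILE", "HG21"): "g2",
    ("LEU", "CD1"): "d1", ("LEU", "HD1"): "d1", ("LEU", "HD11"): "d1",
    ("LEU", "CD2"): "d2", ("LEU", "HD2"): "d2", ("LEU", "HD21"): "d2",
    ("VAL", "CG1"): "g1", ("VAL", "HG1"): "g1", ("VAL", "HG11"): "g1",
    ("VAL", "CG2"): "g2", ("VAL", "HG2"): "g2", ("VAL", "HG21"): "g2",
    ("MET", "CE"): "e", ("MET", "HE"): "e", ("MET", "HE1"): "e",
    ("ALA", "CB"): "b", ("ALA", "HB"): "b", ("ALA", "HB1"): "b",
}


def _read_nmrstar(path: Path) -> list[MethylPeak]:
    """Parse the Atom_chem_shift loop of an NMR-STAR v3 file.

    Minimal reader for the BMRB deposition subset: a ``loop_`` block whose
    tags start with ``_Atom_chem_shift.``; quoted values and stop/save
    terminators are honoured, nothing else of STAR is needed.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = in_shift_loop = reading_rows = False
    for raw in lines:
        line = raw.strip()
        if line == "loop_":
            in_loop, in_shift_loop, reading_rows = True, False, False
            tags = []
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            if line.split(".")[0] == "_Atom_chem_shift":
                in_shift_loop = True
            tags.append(line)
            continue
        if line in {"stop_", "save_"}:
            if in_shift_loop and rows:
                break
            in_loop = in_shift_loop = False
            continue
        if not line or line.startswith("#"):
            continue
        if in_shift_loop:
            reading_rows = True
            rows.append(line.replace('"', " ").replace("'", " ").split())
    if not rows:
        warnings.warn(f"{path}: no Atom_chem_shift loop found; empty peak list")
        return []

    idx = {t.split(".", 1)[1].lower(): i for i, t in enumerate(tags)}

    def col(row: list[str], *names: str) -> str | None:
        for n in names:
            i = idx.get(n.lower())
            if i is not None and i < len(row):
                return row[i]
        return None

    # group per (residue number, residue type, methyl id); combine H + C rows
    groups: dict[tuple[int, str, str], dict[str, float]] = {}
    for row in rows:
        comp = (col(row, "comp_id") or "").upper()
        rtype = _THREE_TO_ONE.get(comp)
        if rtype is None:
            continue
        atom = (col(row, "atom_id") or "").upper()
        mid = _STAR_ATOM_TO_METHYL.get((comp, atom))
        if mid is None:
            continue
        seq = col(row, "seq_id", "comp_index_id", "auth_seq_id")
        val = col(row, "val")
        if seq is None or val is None:
            continue
        key = (int(seq), rtype, mid)
        dim = "H" if atom.startswith("H") else "C"
        groups.setdefault(key, {})[dim] = float(val)

    peaks = []
    for (num, rtype, mid), shifts in sorted(groups.items()):
        if "H" not in shifts or "C" not in shifts:
            warnings.warn(
                f"incomplete shift pair for {rtype}{num}{mid}; skipped"
            )
            continue
        peaks.append(
            MethylPeak(
                delta_H=shifts["H"],
                delta_C=shifts["C"],
                site=MethylSite(num, mid, rtype),
            )
        )
    return peaks


def read_peaklist(
    path: str | Path,
    dialect: str = "sparky",
    state_label: str = "",
    **metadata,
) -> PeakList:
    """Read a peak list in the given dialect into a :class:`PeakList`.

    Parameters
    ----------
    path:
        Input file. Must exist.
    dialect:
        One of ``sparky``, ``nmrstar``, ``csv``.
    state_label, **metadata:
        Stored on the returned :class:`PeakList` (``field_MHz``,
        ``temperature_K``, ``concentration_uM``, ``n_scans_norm``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"sparky": _read_sparky, "nmrstar": _read_nmrstar, "csv": _read_csv}
    if dialect not in readers:
        raise PeakListError(f"unsupported dialect {dialect!r}")
    peaks = readers[dialect](path)
    if not peaks:
        warnings.warn(f"{path}: empty peak list")
    return PeakList(
        state_label=state_label or path.stem, peaks=peaks, **metadata
    )


def write_peaklist(peaklist: PeakList, path: str | Path, dialect: str = "sparky") -> None:
    """Write a peak list; ``sparky`` and ``csv`` dialects are supported."""
    path = Path(path)
    if dialect == "sparky":
        with open(path, "w") as fh:
            fh.write("Assignment w1 w2 Height\n")
            for p in peaklist.peaks:
                token = p.site.label if p.site is not None else "?"
                fh.write(f"{token} {p.delta_H!r} {p.delta_C!r} {p.intensity!r}\n")
    elif dialect == "csv":
        rows = [
            {
                "assignment": p.site.label if p.site is not None else "",
                "delta_H": p.delta_H,
                "delta_C": p.delta_C,
                "intensity": p.intensity,
            }
            for p in peaklist.peaks
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    else:
        raise PeakListError(f"unsupported output dialect {dialect!r}")


# ---------------------------------------------------------------------------
# structure reader


def read_structure(
    path: str | Path,
    mutation_residues: Sequence[int] = (),
    ligand_resname: str | None = None,
    glyco_residues: Sequence[int] = (),
) -> StructureModel:
    """Extract methyl coordinates and reference points from a PDB file.

    Methyl carbons are catalogued per ILVMA residue (CD1 for Ile δ1, CE for
    Met ε, ...). Mutation and glycosylation points are the Cα of the named
    residues; ligand atoms are all heavy atoms of the HETATM residue with
    the given residue name.  First MODEL only, altloc '' or 'A'.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    model = next(structure.get_models())

    methyl_coords: dict[MethylSite, np.ndarray] = {}
    ligand_atoms: list[np.ndarray] = []
    ca_by_resnum: dict[int, np.ndarray] = {}

    for chain in model:
        for residue in chain:
            hetflag, resnum, _ = residue.id
            resname = residue.get_resname().strip().upper()
            if ligand_resname and resname == ligand_resname.upper():
                for atom in residue:
                    if not atom.element == "H":
                        ligand_atoms.append(np.asarray(atom.coord, dtype=float))
                continue
            if hetflag.strip():
                continue
            ca = residue.child_dict.get("CA")
            if ca is not None and resnum not in ca_by_resnum:
                ca_by_resnum[resnum] = np.asarray(ca.coord, dtype=float)
            rtype = _THREE_TO_ONE.get(resname)
            if rtype is None:
                continue
            for mid in METHYL_IDS_BY_RESIDUE[rtype]:
                atom_name = METHYL_ATOM_NAMES[(rtype, mid)]
                atom = residue.child_dict.get(atom_name)
                if atom is None:
                    continue
                if atom.is_disordered():
                    atom = atom.disordered_get("A")
                site = MethylSite(resnum, mid, rtype)
                if site not in methyl_coords:
                    methyl_coords[site] = np.asarray(atom.coord, dtype=float)

    if not methyl_coords:
        raise PeakListError(f"{path}: no ILVMA methyl atoms found")

    mutation_points = []
    for resnum in mutation_residues:
        if resnum not in ca_by_resnum:
            raise PeakListError(f"{path}: mutation residue {resnum} not found")
        mutation_points.append((str(resnum), ca_by_resnum[resnum]))

    glyco_points = []
    for resnum in glyco_residues:
        if resnum not in ca_by_resnum:
            raise PeakListError(f"{path}: glycosylation residue {resnum} not found")
        glyco_points.append((str(resnum), ca_by_resnum[resnum]))

    if ligand_resname and not ligand_atoms:
        warnings.warn(f"{path}: ligand residue {ligand_resname!r} not found")

    return StructureModel(
        methyl_coords=methyl_coords,
        mutation_points=mutation_points,
        ligand_atoms=ligand_atoms,
        glycosite_points=glyco_points,
    )


# ---------------------------------------------------------------------------
# result tables


def write_results_table(records: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a tabular result as TSV with deterministic formatting.

    Columns keep their input order; floats are printed with 6 significant
    digits. Empty input is an error — an empty result almost always means an
    upstream stage silently produced nothing.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty:
        raise PeakListError("refusing to write an empty results table")

    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return f"{v:.6g}"
        return v

    df.map(fmt).to_csv(path, sep="\t", index=False)
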