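"""Structure input/output: chain extraction, quality filters, solvent accessibility.

Structures are reduced to :class:`ChainModel` objects — ordered standard
amino-acid residues with heavy-atom coordinates plus the crystallographic
quality metadata (resolution, R factors) needed for dataset filtering.
Parsing is delegated to gemmi, which handles both PDB and mmCIF dialects.

Conventions
-----------
* Hydrogens and deuteriums are kept in the atom list but flagged
  ``is_heavy=False``; contacts and solvent accessibility use heavy atoms only.
* Alternate locations are resolved to the highest-occupancy copy (first in
  file on ties).
* Selenomethionine (MSE) is mapped to MET; other non-standard residues,
  ligands and waters are dropped.
* Residues are ordered by author numbering ``(seq_number, insertion_code)``
  and indexed internally by a contiguous 0-based ``sequence_index``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

STANDARD_AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: substitutions applied before the standard-residue filter
NONSTANDARD_MAP = {"MSE": "MET"}

#: van der Waals radii (Å) by element, used for solvent accessibility
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80,
    "H": 1.20, "D": 1.20,
}
DEFAULT_VDW = 1.80

#: theoretical maximum accessible surface areas (Å², Tien et al. 2013),
#: denominators of relative solvent accessibility
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class StructureParseError(ValueError):
    """Raised when a structure file cannot be read under the requested dialect."""


@dataclass
class AtomRecord:
    """One atom: name token, element symbol, position (Å), occupancy, altloc."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_heavy: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class ResidueUnit:
    """One amino-acid residue: author identity, type, and its atoms."""

    chain_id: str
    seq_number: int
    insertion_code: str
    name3: str
    atoms: list[AtomRecord]
    sequence_index: int = -1

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name3]

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def ca(self) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == "CA" and a.is_heavy:
                return a
        return None

    @property
    def label(self) -> str:
        """Author-numbering label, e.g. ``A:304`` or ``A:52B``."""
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"


@dataclass
class ChainModel:
    """A single polymer chain plus structure-level quality metadata."""

    pdb_id: str
    chain_id: str
    residues: list[ResidueUnit]
    resolution: float | None = None
    r_free: float | None = None
    r_work: float | None = None

    def __post_init__(self):
        keys = [(r.seq_number, r.insertion_code) for r in self.residues]
        if keys != sorted(keys):
            self.residues = sorted(
                self.residues, key=lambda r: (r.seq_number, r.insertion_code)
            )
        for i, res in enumerate(self.residues):
            res.sequence_index = i

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates; NaN rows for residues without a Cα."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.ca
            if ca is not None:
                out[i] = ca.position
        return out

    def heavy_atom_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(coords, residue_index) arrays over all heavy atoms, in residue order."""
        coords, idx = [], []
        for i, res in enumerate(self.residues):
            for a in res.heavy_atoms:
                coords.append(a.position)
                idx.append(i)
        return np.asarray(coords, float).reshape(-1, 3), np.asarray(idx, int)


@dataclass
class ExposureProfile:
    """Per-residue solvent accessibility: absolute (Å²), relative, and class."""

    labels: list[str]
    absolute: np.ndarray
    relative: np.ndarray
    classes: list[str | None]  # "buried" / "exposed" / None (no reference maximum)
    probe_radius: float = 1.4
    rsa_threshold: float = 0.10


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one copy per atom name: highest occupancy, first-in-file on ties."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > best[atom.name].occupancy:
            best[atom.name] = atom
    return [best[name] for name in order]


def _r_factors_from_remarks(remarks: Iterable[str]) -> tuple[float | None, float | None]:
    r_work = r_free = None
    pat_work = re.compile(r"R VALUE\s+\(WORKING SET\)\s*:\s*([\d.]+)")
    pat_free = re.compile(r"FREE R VALUE\s*:\s*([\d.]+)")
    for line in remarks:
        if not line.startswith("REMARK   3"):
            continue
        m = pat_work.search(line)
        if m and r_work is None:
            r_work = float(m.group(1))
        m = pat_free.search(line)
        if m and r_free is None:
            r_free = float(m.group(1))
    return r_free, r_work


def read_structure(path: str | Path, dialect: str | None = None) -> list[ChainModel]:
    """Read a PDB or mmCIF file into one :class:`ChainModel` per polymer chain.

    Parameters
    ----------
    path
        Structure file.  ``dialect`` may be ``"pdb"`` or ``"mmcif"``; when
        omitted it is inferred from the extension.
    """
    import gemmi

    path = Path(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        elif dialect == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {dialect}: {exc}") from exc

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    r_free = r_work = None
    if dialect == "pdb":
        r_free, r_work = _r_factors_from_remarks(st.raw_remarks)
    else:
        for ref in st.meta.refinement:
            if ref.r_free is not None and not math.isnan(ref.r_free):
                r_free = ref.r_free
            if ref.r_work is not None and not math.isnan(ref.r_work):
                r_work = ref.r_work

    pdb_id = st.name or path.stem
    chains: list[ChainModel] = []
    model = st[0]
    for chain in model:
        residues: list[ResidueUnit] = []
        for res in chain:
            name3 = NONSTANDARD_MAP.get(res.name, res.name)
            if name3 not in THREE_TO_ONE:
                if res.name not in {"HOH", "DOD"} and res.het_flag != "H":
                    logger.warning(
                        "%s chain %s: dropping non-standard residue %s %d",
                        pdb_id, chain.name, res.name, res.seqid.num,
                    )
                continue
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name.upper(),
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc="" if a.altloc == "\0" else a.altloc,
                    is_heavy=a.element.name.upper() not in _HYDROGEN_ELEMENTS,
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            residues.append(
                ResidueUnit(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    name3=name3,
                    atoms=atoms,
                )
            )
        if not residues:
            logger.warning("%s chain %s: no standard residues, chain omitted", pdb_id, chain.name)
            continue
        chains.append(
            ChainModel(
                pdb_id=pdb_id,
                chain_id=chain.name,
                residues=residues,
                resolution=resolution,
                r_free=r_free,
                r_work=r_work,
            )
        )
    return chains


# ---------------------------------------------------------------------------
# writing


def write_pdb(chains: ChainModel | Sequence[ChainModel], path: str | Path) -> None:
    """Serialize chains as fixed-column PDB text (ATOM records, quality remarks)."""
    if isinstance(chains, ChainModel):
        chains = [chains]
    lines: list[str] = []
    first = chains[0]
    if first.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {first.resolution:.2f} ANGSTROMS.")
    if first.r_work is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : {first.r_work:.3f}")
    if first.r_free is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : {first.r_free:.3f}")
    serial = 1
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # PDB column rule: 4-char field; names < 4 chars start in col 14
                field_name = name if len(name) >= 4 else f" {name:<3s}"
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {field_name}{'' if atom.altloc else ' '}"
                    f"{atom.altloc or ''}"
                    f"{res.name3:>3s} {chain.chain_id[:1]}{res.seq_number:4d}"
                    f"{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# quality filter


def quality_filter(
    chain: ChainModel, max_resolution: float = 3.0, max_r_diff: float = 0.05
) -> bool:
    """Crystallographic quality predicate used for dataset selection.

    True iff resolution is present and ≤ ``max_resolution`` and, when both R
    factors are present, ``r_free − r_work ≤ max_r_diff``.  Missing resolution
    fails; missing R factors pass with a logged warning.
    """
    if chain.resolution is None or chain.resolution > max_resolution:
        return False
    if chain.r_free is None or chain.r_work is None:
        logger.warning(
            "%s chain %s: R factors absent, accepting on resolution alone",
            chain.pdb_id, chain.chain_id,
        )
        return True
    # small epsilon keeps the inclusive boundary robust to float representation
    return (chain.r_free - chain.r_work) <= max_r_diff + 1e-9


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake–Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by sphere-point sampling.

    Each atom is expanded by the probe radius; the accessible area is the
    fraction of lattice points on its expanded sphere not contained in any
    neighbouring expanded sphere.
    """
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe_radius
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
                      if j != i]
        accessible = np.ones(n_points, bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def compute_exposure(
    chain: ChainModel,
    probe_radius: float = 1.4,
    rsa_threshold: float = 0.10,
    n_points: int = 960,
) -> ExposureProfile:
    """Per-residue SASA, relative SASA and buried/exposed class for a chain.

    Heavy atoms only.  Relative SASA divides by the residue type's theoretical
    maximum; residues with no reference maximum get class ``None``.
    """
    coords, res_idx = chain.heavy_atom_table()
    if coords.size == 0:
        raise ValueError("chain has no heavy atoms")
    elements = [a.element for r in chain.residues for a in r.heavy_atoms]
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements])
    atom_area = shrake_rupley_sasa(coords, radii, probe_radius, n_points)

    n_res = len(chain.residues)
    absolute = np.zeros(n_res)
    np.add.at(absolute, res_idx, atom_area)
    relative = np.zeros(n_res)
    classes: list[str | None] = []
    for i, res in enumerate(chain.residues):
        ref = MAX_ASA.get(res.name3)
        if ref is None:
            relative[i] = np.nan
            classes.append(None)
            logger.warning("no reference maximum for %s; class undefined", res.name3)
        else:
            relative[i] = absolute[i] / ref
            classes.append("buried" if relative[i] < rsa_threshold else "exposed")
    return ExposureProfile(
        labels=[r.label for r in chain.residues],
        absolute=absolute,
        relative=relative,
        classes=classes,
        probe_radius=probe_radius,
        rsa_threshold=rsa_threshold,
    )
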