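"""Structure I/O: PDBQT/PDB parsing, atom typing and the in-memory pose model.

The canonical pose format is PDBQT (the AutoDock/Vina dialect of PDB).
Receptors and crystal ligands may also be supplied as plain PDB, in which
case the element is inferred from the atom-name/element columns and a
conservative AutoDock type is assigned.

Atom interaction-role flags (hydrophobic, H-bond donor/acceptor) are
derived deterministically from the AutoDock atom type plus a
distance-based covalent bond detection, so the same file always parses to
the same flags.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TypedAtom",
    "Receptor",
    "PoseRecord",
    "PoseSet",
    "PDBQTParseError",
    "read_pdbqt",
    "read_pdb_receptor",
    "write_pdbqt",
    "define_search_box",
    "detect_bonds",
    "movable_pairs",
    "count_rotatable_bonds",
]


class PDBQTParseError(ValueError):
    """Raised for malformed ATOM/HETATM records; carries the line number."""


# AutoDock type -> chemical element
_AD_TO_ELEMENT = {
    "C": "C", "A": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "H": "H", "HD": "H", "HS": "H",
    "P": "P", "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "ZN": "Zn", "MG": "Mg", "MN": "Mn", "CA": "Ca", "FE": "Fe",
    "CU": "Cu", "NI": "Ni", "CO": "Co", "CD": "Cd", "K": "K", "NA+": "Na",
}

_METALS = {"Zn", "Mg", "Mn", "Ca", "Fe", "Cu", "Ni", "Co", "Cd", "K", "Na"}

_LIGAND_ELEMENTS = {"C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "H"}
_PROTEIN_ELEMENTS = {"C", "N", "O", "S", "H"} | _METALS

# single-bond covalent radii, Angstrom (used only for bond detection)
_COVALENT_RADIUS = {
    "H": 0.37, "C": 0.77, "N": 0.75, "O": 0.73, "F": 0.71,
    "P": 1.06, "S": 1.02, "Cl": 0.99, "Br": 1.14, "I": 1.33,
}
_METAL_COVALENT_RADIUS = 1.30

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"}

_HBOND_ACCEPTOR_AD_TYPES = {"OA", "NA", "SA"}


@dataclass
class TypedAtom:
    """One atom with coordinates, element and interaction-role flags."""

    serial: int
    name: str
    coords: np.ndarray  # shape (3,), Angstrom
    element: str
    ad_type: str
    is_hydrophobic: bool = False
    is_hbond_donor: bool = False
    is_hbond_acceptor: bool = False
    resname: str = "LIG"
    chain: str = "A"
    resseq: int = 1
    charge: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"atom serial {self.serial}: coordinates must be three finite numbers"
            )

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_metal(self) -> bool:
        return self.element in _METALS


@dataclass
class Receptor:
    """A protein structure: waters removed, recognised metal ions retained."""

    id: str
    atoms: list[TypedAtom]

    def heavy_atoms(self) -> list[TypedAtom]:
        return [a for a in self.atoms if a.is_heavy]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class PoseRecord:
    """One ligand pose; ``rank`` is 1-based for docked poses."""

    atoms: list[TypedAtom]
    vina_energy: float = math.nan  # kcal/mol
    rank: int = 1
    source: str = "docked"  # {"crystal", "docked"}

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose must contain at least one atom")
        if self.source == "docked" and not 1 <= self.rank <= 9:
            raise ValueError(f"docked pose rank must be in [1, 9], got {self.rank}")

    def heavy_atoms(self) -> list[TypedAtom]:
        return [a for a in self.atoms if a.is_heavy]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class PoseSet:
    """All poses of one ligand: optional crystal pose plus up to 9 docked.

    ``bonds`` is the covalent adjacency over atom indices of the reference
    pose (crystal if present, else first docked); atom order is identical
    across all poses of a ligand (Vina preserves input order).
    """

    ligand_id: str
    nrot: int = 0
    crystal: PoseRecord | None = None
    docked: list[PoseRecord] = field(default_factory=list)
    measured_affinity: float | None = None  # pKd
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nrot < 0:
            raise ValueError("nrot must be non-negative")
        if len(self.docked) > 9:
            raise ValueError("at most 9 docked poses are supported")
        self.sort_docked()

    def sort_docked(self) -> None:
        """Sort docked poses ascending by vina_energy and renumber ranks."""
        self.docked.sort(key=lambda p: (p.vina_energy, p.rank))
        for i, pose in enumerate(self.docked, start=1):
            pose.rank = i

    def reference_pose(self) -> PoseRecord:
        if self.crystal is not None:
            return self.crystal
        if self.docked:
            return self.docked[0]
        raise ValueError(f"pose set {self.ligand_id!r} contains no poses")

    def all_poses(self) -> list[PoseRecord]:
        poses = list(self.docked)
        if self.crystal is not None:
            poses = [self.crystal] + poses
        return poses


def _element_from_ad_type(ad_type: str, lineno: int) -> str:
    elem = _AD_TO_ELEMENT.get(ad_type.upper())
    if elem is None:
        raise PDBQTParseError(f"line {lineno}: unsupported AutoDock type {ad_type!r}")
    return elem


def _parse_atom_line(line: str, lineno: int) -> TypedAtom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip() or "LIG"
        chain = line[21:22].strip() or "A"
        resseq = int(line[22:26]) if line[22:26].strip() else 1
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBQTParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    charge = 0.0
    if len(line) >= 76 and line[70:76].strip():
        try:
            charge = float(line[70:76])
        except ValueError:
            charge = 0.0
    ad_type = line[77:79].strip() if len(line) > 77 else ""
    if not ad_type:
        # fall back to last whitespace token (tolerates ragged columns)
        ad_type = line.split()[-1]
    element = _element_from_ad_type(ad_type, lineno)
    return TypedAtom(
        serial=serial, name=name, coords=np.array([x, y, z]),
        element=element, ad_type=ad_type.upper(),
        resname=resname, chain=chain, resseq=resseq, charge=charge,
    )


def detect_bonds(atoms: Sequence[TypedAtom]) -> list[tuple[int, int]]:
    """Detect covalent bonds from interatomic distances.

    Two atoms are bonded when their distance is below 1.25x the sum of
    their single-bond covalent radii. Metals are never bonded (treated as
    free ions).
    """
    n = len(atoms)
    bonds: list[tuple[int, int]] = []
    radii = np.array(
        [
            _METAL_COVALENT_RADIUS if a.is_metal else _COVALENT_RADIUS.get(a.element, 0.77)
            for a in atoms
        ]
    )
    coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
    for i in range(n):
        if atoms[i].is_metal:
            continue
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cut = 1.25 * (radii[i] + radii[i + 1:])
        for off in np.nonzero(d < cut)[0]:
            j = i + 1 + int(off)
            if not atoms[j].is_metal:
                bonds.append((i, j))
    return bonds


def _adjacency(n: int, bonds: Iterable[tuple[int, int]]) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def assign_role_flags(atoms: Sequence[TypedAtom], bonds: Sequence[tuple[int, int]]) -> None:
    """Assign hydrophobic/donor/acceptor flags in place (Vina conventions).

    hydrophobic: carbon with no bonded N/O, or a halogen;
    donor: heavy atom carrying a bonded polar hydrogen (AD type HD), or a metal;
    acceptor: AD types OA / NA / SA.
    """
    adj = _adjacency(len(atoms), bonds)
    for idx, atom in enumerate(atoms):
        neighbors = [atoms[j] for j in adj[idx]]
        atom.is_hbond_acceptor = atom.ad_type in _HBOND_ACCEPTOR_AD_TYPES
        atom.is_hbond_donor = atom.is_metal or any(
            nb.ad_type == "HD" for nb in neighbors
        )
        if atom.element == "C":
            atom.is_hydrophobic = not any(nb.element in ("N", "O") for nb in neighbors)
        elif atom.element in ("F", "Cl", "Br", "I"):
            atom.is_hydrophobic = True
        else:
            atom.is_hydrophobic = False


def count_rotatable_bonds(atoms: Sequence[TypedAtom], bonds: Sequence[tuple[int, int]]) -> int:
    """Count rotatable bonds: acyclic single bonds between non-terminal heavy atoms.

    A bond is terminal when either end has no other heavy neighbour. Ring
    membership is decided by connectivity (removing the bond leaves the two
    ends connected). Bond orders are not available from PDBQT, so all
    detected bonds are treated as single bonds.
    """
    n = len(atoms)
    adj = _adjacency(n, bonds)

    def heavy_degree(i: int) -> int:
        return sum(1 for j in adj[i] if atoms[j].is_heavy)

    def connected_without(a: int, b: int) -> bool:
        seen = {a}
        queue = deque([a])
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur]:
                if (cur, nxt) in ((a, b), (b, a)):
                    continue
                if nxt == b:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        return False

    nrot = 0
    for i, j in bonds:
        if not (atoms[i].is_heavy and atoms[j].is_heavy):
            continue
        if heavy_degree(i) < 2 or heavy_degree(j) < 2:
            continue  # terminal
        if connected_without(i, j):
            continue  # in a ring -> not rotatable
        nrot += 1
    return nrot


def movable_pairs(pose_set: PoseSet) -> list[tuple[int, int]]:
    """Ligand atom-index pairs whose relative position can change.

    A pair is movable when the bond-graph separation between the two atoms
    is at least 4 bonds (more than three consecutive covalent bonds). With
    no rotatable bonds the ligand is rigid and no pair is movable.
    """
    ref = pose_set.reference_pose()
    atoms = ref.atoms
    n = len(atoms)
    if pose_set.nrot == 0:
        return []
    adj = _adjacency(n, pose_set.bonds)

    # all-pairs BFS graph distances (small molecules: n is tiny)
    pairs: list[tuple[int, int]] = []
    for start in range(n):
        dist = [-1] * n
        dist[start] = 0
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur]:
                if dist[nxt] < 0:
                    dist[nxt] = dist[cur] + 1
                    queue.append(nxt)
        for other in range(start + 1, n):
            if dist[other] >= 4 or dist[other] < 0:
                pairs.append((start, other))
    return pairs


def _finalize_pose_set(pose_set: PoseSet) -> PoseSet:
    ref = pose_set.reference_pose()
    if not pose_set.bonds:
        pose_set.bonds = detect_bonds(ref.atoms)
    for pose in pose_set.all_poses():
        assign_role_flags(pose.atoms, pose_set.bonds)
    return pose_set


def read_pdbqt(
    path: str | Path,
    role: str = "ligand",
    *,
    ligand_id: str | None = None,
    skip_unsupported: bool = False,
) -> Receptor | PoseSet:
    """Parse a PDBQT file into a :class:`Receptor` or :class:`PoseSet`.

    For ``role="ligand"`` each MODEL block becomes one :class:`PoseRecord`;
    ``REMARK VINA RESULT`` supplies the pose energy and ``TORSDOF`` the
    rotatable-bond count (recomputed from connectivity when absent).
    For ``role="receptor"`` waters are removed and metal ions retained.

    Parameters
    ----------
    skip_unsupported:
        When true, atoms with unrecognised AutoDock types are skipped with
        a warning instead of raising.
    """
    if role not in ("receptor", "ligand"):
        raise ValueError(f"role must be 'receptor' or 'ligand', got {role!r}")
    path = Path(path)
    text = path.read_text()
    name = ligand_id or path.stem

    models: list[dict] = []
    current: dict = {"atoms": [], "energy": math.nan, "torsdof": None}
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = {"atoms": [], "energy": math.nan, "torsdof": None}
        elif rec == "ENDMDL":
            models.append(current)
        elif rec in ("ATOM", "HETATM"):
            try:
                atom = _parse_atom_line(line, lineno)
            except PDBQTParseError:
                if skip_unsupported:
                    import warnings

                    warnings.warn(f"{path}: skipping unparsable atom at line {lineno}")
                    continue
                raise
            current["atoms"].append(atom)
        elif rec == "REMARK" and "VINA RESULT" in line:
            fields = line.split()
            idx = fields.index("RESULT:") if "RESULT:" in fields else 3
            current["energy"] = float(fields[idx + 1])
        elif rec == "TORSDO" or line.startswith("TORSDOF"):
            current["torsdof"] = int(line.split()[1])
    if not saw_model and current["atoms"]:
        models.append(current)

    if role == "receptor":
        atoms = [
            a
            for m in models
            for a in m["atoms"]
            if a.resname not in _WATER_RESNAMES
        ]
        bonds = detect_bonds(atoms)
        assign_role_flags(atoms, bonds)
        return Receptor(id=name, atoms=atoms)

    poses = []
    torsdof = None
    for k, m in enumerate(models, start=1):
        if not m["atoms"]:
            continue
        poses.append(
            PoseRecord(atoms=m["atoms"], vina_energy=m["energy"], rank=min(k, 9))
        )
        if m["torsdof"] is not None:
            torsdof = m["torsdof"]
    if not poses:
        raise PDBQTParseError(f"{path}: no atoms found")
    first_atoms = poses[0].atoms
    bonds = detect_bonds(first_atoms)
    if torsdof is None:
        torsdof = count_rotatable_bonds(first_atoms, bonds)
    pose_set = PoseSet(ligand_id=name, nrot=torsdof, docked=poses[:9], bonds=bonds)
    return _finalize_pose_set(pose_set)


# PDB v3.3 two-character element symbols appearing in atom-name columns
_PDB_NAME_ELEMENTS = {"CL": "Cl", "BR": "Br", "ZN": "Zn", "MG": "Mg", "FE": "Fe",
                      "MN": "Mn", "CA": "Ca", "NA": "Na", "CU": "Cu", "NI": "Ni"}


def read_pdb_receptor(path: str | Path) -> Receptor:
    """Read a plain PDB receptor; element from columns 77-78 or atom name."""
    path = Path(path)
    atoms: list[TypedAtom] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line[:6].strip() not in ("ATOM", "HETATM"):
            continue
        resname = line[17:20].strip()
        if resname in _WATER_RESNAMES:
            continue
        elem = line[76:78].strip().capitalize() if len(line) >= 78 else ""
        if not elem:
            raw = line[12:16].strip()
            elem = _PDB_NAME_ELEMENTS.get(raw[:2].upper(), raw[:1].upper())
        ad_type = {"C": "C", "N": "N", "O": "OA", "S": "SA", "H": "H"}.get(
            elem, elem.upper()
        )
        try:
            atom = TypedAtom(
                serial=int(line[6:11]),
                name=line[12:16].strip(),
                coords=np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                ),
                element=elem,
                ad_type=ad_type,
                resname=resname,
                chain=line[21:22].strip() or "A",
                resseq=int(line[22:26]) if line[22:26].strip() else 1,
            )
        except (ValueError, IndexError) as exc:
            raise PDBQTParseError(f"line {lineno}: malformed record: {exc}") from exc
        atoms.append(atom)
    bonds = detect_bonds(atoms)
    assign_role_flags(atoms, bonds)
    return Receptor(id=path.stem, atoms=atoms)


def _format_atom_line(atom: TypedAtom) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
    return (
        f"ATOM  {atom.serial:5d} {name:<4} {atom.resname:<3} "
        f"{atom.chain:1}{atom.resseq:4d}    "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}    {atom.charge:6.3f} {atom.ad_type:<2}"
    )


def write_pdbqt(obj: Receptor | PoseSet, path: str | Path, *, which: str = "docked") -> None:
    """Write a receptor or a pose set as PDBQT.

    For a :class:`PoseSet`, ``which`` selects ``"docked"`` (multi-MODEL with
    REMARK VINA RESULT lines) or ``"crystal"`` (single block).
    """
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, Receptor):
        lines.extend(_format_atom_line(a) for a in obj.atoms)
        lines.append("TER")
    else:
        if which == "crystal":
            if obj.crystal is None:
                raise ValueError(f"pose set {obj.ligand_id!r} has no crystal pose")
            lines.append(f"REMARK  LIGAND {obj.ligand_id}")
            lines.extend(_format_atom_line(a) for a in obj.crystal.atoms)
            lines.append(f"TORSDOF {obj.nrot}")
        else:
            for pose in obj.docked:
                lines.append(f"MODEL {pose.rank:8d}")
                if math.isfinite(pose.vina_energy):
                    lines.append(
                        f"REMARK VINA RESULT: {pose.vina_energy:12.4f}"
                        f"{0.0:11.3f}{0.0:11.3f}"
                    )
                lines.extend(_format_atom_line(a) for a in pose.atoms)
                lines.append(f"TORSDOF {obj.nrot}")
                lines.append("ENDMDL")
    path.write_text("\n".join(lines) + "\n")


def define_search_box(ligand: PoseRecord, margin: float = 10.0) -> tuple[np.ndarray, float]:
    """Smallest cube covering the ligand, each face extended by ``margin`` A.

    Returns ``(center, edge_length)``. Used only for interoperability with
    external docking runs; scoring never consults the box.
    """
    if not ligand.atoms:
        raise ValueError("cannot define a search box for an empty pose")
    coords = np.array([a.coords for a in ligand.atoms]).reshape(-1, 3)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    center = (lo + hi) / 2.0
    edge = float(np.max(hi - lo)) + 2.0 * margin
    return center, edge
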