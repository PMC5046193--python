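"""Synthetic complexes with controlled pose error and known affinity law.

Every other module is testable without downloads: receptors are shells of
typed atoms around a pocket, ligands are self-avoiding heavy-atom chains
(with polar hydrogens on nitrogens so donor flags round-trip through
PDBQT), docked poses are rigid transforms plus optional per-atom jitter of
the crystal pose, and affinities are drawn from a configurable function of
the implemented features with returned ground-truth parameters.

No physical realism is intended beyond overlap avoidance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .schemes import SchemeSpec, assemble_features, feature_names
from .structures import (
    PoseRecord,
    PoseSet,
    Receptor,
    TypedAtom,
    assign_role_flags,
    count_rotatable_bonds,
    detect_bonds,
    movable_pairs,
    read_pdbqt,
    write_pdbqt,
)
from .vina import (
    DEFAULT_WEIGHTS,
    PKD_PER_KCAL,
    compute_terms,
    vina_score,
    weighted_energy,
)

__all__ = [
    "FixtureConfig",
    "SyntheticDataset",
    "make_complex",
    "make_dataset",
    "write_fixture_tree",
    "load_fixture_tree",
]

_LIGAND_AD_TYPE = {
    "C": "C", "N": "N", "O": "OA", "S": "S",
    "F": "F", "P": "P", "Cl": "CL", "Br": "BR", "I": "I",
}
_RECEPTOR_AD_TYPE = {"C": "C", "N": "N", "O": "OA", "S": "SA"}

_DEFAULT_LIGAND_FREQS = {
    "C": 0.70, "N": 0.12, "O": 0.12, "S": 0.02,
    "F": 0.01, "P": 0.01, "Cl": 0.01, "Br": 0.005, "I": 0.005,
}
_DEFAULT_RECEPTOR_FREQS = {"C": 0.65, "N": 0.15, "O": 0.15, "S": 0.05}

_BOND_LENGTH = 1.5
_MIN_NONBONDED = 2.4
_MAX_TRIES = 200


@dataclass
class FixtureConfig:
    n_complexes: int = 30
    protein_atoms: tuple[int, int] = (40, 80)
    ligand_atoms: tuple[int, int] = (8, 16)  # heavy atoms
    ligand_element_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_LIGAND_FREQS))
    receptor_element_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_RECEPTOR_FREQS))
    n_poses: int = 5
    translation: float = 1.0  # A, exact rigid-shift magnitude per docked pose
    rotation_deg: float = 20.0
    jitter: float = 0.1  # per-atom Gaussian sd, A
    metal_prob: float = 0.0
    affinity_model: str = "linear-vina"  # {linear-vina, vina, linear-contacts, nonlinear}
    label_scheme: int = 1  # scheme supplying the features that generate y
    feature_set: str = "vina11"
    d_cutoff: float = 12.0
    w6_true: float = 0.02
    noise_sd: float = 0.0
    affinity_span: float = 6.0  # target pKd range of generated affinities
    seed: int = 0


def _sample_elements(rng: np.random.Generator, freqs: dict, n: int) -> list[str]:
    elems = list(freqs)
    probs = np.array([freqs[e] for e in elems], dtype=float)
    probs /= probs.sum()
    return list(rng.choice(elems, size=n, p=probs))


def _grow_chain(rng: np.random.Generator, n: int) -> np.ndarray:
    """Self-avoiding random chain, bond length 1.5 A, non-bonded >= 2.4 A."""
    coords = [np.zeros(3)]
    while len(coords) < n:
        placed = False
        for _ in range(_MAX_TRIES):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = coords[-1] + _BOND_LENGTH * direction
            prev = np.array(coords[:-1]).reshape(-1, 3)
            if len(prev) == 0 or np.all(
                np.linalg.norm(prev - cand, axis=1) >= _MIN_NONBONDED
            ):
                coords.append(cand)
                placed = True
                break
        if not placed:
            raise RuntimeError("infeasible ligand geometry: retry budget exhausted")
    return np.array(coords)


def _make_ligand_atoms(rng: np.random.Generator, cfg: FixtureConfig) -> list[TypedAtom]:
    n_heavy = int(rng.integers(cfg.ligand_atoms[0], cfg.ligand_atoms[1] + 1))
    elements = _sample_elements(rng, cfg.ligand_element_freqs, n_heavy)
    # halogens and P only at chain ends keeps valence vaguely plausible
    coords = _grow_chain(rng, n_heavy)
    coords -= coords.mean(axis=0)
    atoms = []
    serial = 1
    for i, (elem, xyz) in enumerate(zip(elements, coords)):
        atoms.append(
            TypedAtom(
                serial=serial,
                name=f"{elem}{i + 1}"[:4],
                coords=xyz,
                element=elem,
                ad_type=_LIGAND_AD_TYPE[elem],
            )
        )
        serial += 1
        if elem == "N":  # polar hydrogen so the donor flag round-trips
            lo = max(0, i - 1)
            hi = min(n_heavy - 1, i + 1)
            away = xyz - (coords[lo] + coords[hi]) / 2.0
            norm = np.linalg.norm(away)
            away = away / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            atoms.append(
                TypedAtom(
                    serial=serial,
                    name=f"H{i + 1}"[:4],
                    coords=xyz + 1.0 * away,
                    element="H",
                    ad_type="HD",
                )
            )
            serial += 1
    return atoms


def _make_receptor_atoms(
    rng: np.random.Generator, cfg: FixtureConfig, ligand_coords: np.ndarray
) -> list[TypedAtom]:
    n = int(rng.integers(cfg.protein_atoms[0], cfg.protein_atoms[1] + 1))
    elements = _sample_elements(rng, cfg.receptor_element_freqs, n)
    lig_extent = float(np.max(np.linalg.norm(ligand_coords, axis=1)))
    r_in, r_out = lig_extent + 3.4, lig_extent + 8.0
    placed: list[np.ndarray] = []
    atoms: list[TypedAtom] = []
    for i, elem in enumerate(elements):
        ok = False
        for _ in range(_MAX_TRIES):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(r_in, r_out)
            cand = radius * direction
            if placed and np.min(
                np.linalg.norm(np.array(placed) - cand, axis=1)
            ) < 2.0:
                continue
            if np.min(np.linalg.norm(ligand_coords - cand, axis=1)) < 3.0:
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError("infeasible receptor geometry: retry budget exhausted")
        placed.append(cand)
        atoms.append(
            TypedAtom(
                serial=i + 1,
                name=f"{elem}{i + 1}"[:4],
                coords=cand,
                element=elem,
                ad_type=_RECEPTOR_AD_TYPE[elem],
                resname="REC",
            )
        )
    if rng.uniform() < cfg.metal_prob:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        atoms.append(
            TypedAtom(
                serial=len(atoms) + 1,
                name="ZN",
                coords=(r_in + 0.5) * direction,
                element="Zn",
                ad_type="ZN",
                resname="ZN",
            )
        )
    return atoms


def _perturbed_pose(
    rng: np.random.Generator, crystal: PoseRecord, cfg: FixtureConfig
) -> PoseRecord:
    coords = crystal.coords(heavy_only=False)
    centroid = coords.mean(axis=0)
    if cfg.rotation_deg > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.uniform(0, cfg.rotation_deg))
        rot = Rotation.from_rotvec(angle * axis)
        coords = rot.apply(coords - centroid) + centroid
    if cfg.translation > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords = coords + cfg.translation * direction
    if cfg.jitter > 0:
        coords = coords + rng.normal(scale=cfg.jitter, size=coords.shape)
    atoms = [
        TypedAtom(
            serial=a.serial, name=a.name, coords=c, element=a.element,
            ad_type=a.ad_type, is_hydrophobic=a.is_hydrophobic,
            is_hbond_donor=a.is_hbond_donor, is_hbond_acceptor=a.is_hbond_acceptor,
        )
        for a, c in zip(crystal.atoms, coords)
    ]
    return PoseRecord(atoms=atoms, rank=1, source="docked")


def make_complex(
    cfg: FixtureConfig,
    rng: np.random.Generator | None = None,
    complex_id: str = "cmpl0001",
) -> tuple[Receptor, PoseSet]:
    """Generate one receptor + pose set with Vina-scored docked poses."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lig_atoms = _make_ligand_atoms(rng, cfg)
    heavy_coords = np.array([a.coords for a in lig_atoms if a.is_heavy])
    rec_atoms = _make_receptor_atoms(rng, cfg, heavy_coords)
    assign_role_flags(rec_atoms, detect_bonds(rec_atoms))
    receptor = Receptor(id=f"{complex_id}_rec", atoms=rec_atoms)

    crystal = PoseRecord(atoms=lig_atoms, rank=1, source="crystal")
    bonds = detect_bonds(lig_atoms)
    nrot = count_rotatable_bonds(lig_atoms, bonds)
    docked = [_perturbed_pose(rng, crystal, cfg) for _ in range(cfg.n_poses)]

    pose_set = PoseSet(
        ligand_id=complex_id, nrot=nrot, crystal=crystal, docked=docked, bonds=bonds
    )
    for pose in pose_set.all_poses():
        assign_role_flags(pose.atoms, bonds)

    # score docked poses: the lowest raw (inter+intra) pose is the intra reference
    pairs = movable_pairs(pose_set)
    raw = []
    for pose in docked:
        t = compute_terms(receptor, pose, nrot, pairs)
        raw.append((t, weighted_energy(t.inter) + weighted_energy(t.intra)))
    ref_intra = weighted_energy(min(raw, key=lambda te: te[1])[0].intra)
    for pose, (t, _) in zip(docked, raw):
        pose.vina_energy = vina_score(t, ref_intra)
    pose_set.sort_docked()
    return receptor, pose_set


@dataclass
class SyntheticDataset:
    """Generated complexes with affinities and the generating truth."""

    complexes: list[tuple[Receptor, PoseSet]]
    y: np.ndarray
    truth: dict
    config: FixtureConfig

    def feature_matrix(self, scheme_id: int, feature_set: str | None = None) -> np.ndarray:
        fs = feature_set or self.config.feature_set
        spec = SchemeSpec(scheme_id, fs)
        return np.array(
            [
                assemble_features(ps, spec, rec, self.config.d_cutoff).values
                for rec, ps in self.complexes
            ]
        )

    @property
    def ids(self) -> list[str]:
        return [ps.ligand_id for _, ps in self.complexes]


def _affinity_function(cfg: FixtureConfig, X: np.ndarray, rng: np.random.Generator):
    """Return (y_clean, truth dict) for the configured affinity model."""
    nrot = X[:, -1]
    if cfg.affinity_model == "vina":
        # exactly what the fixed-Vina model computes from these features
        e = (X[:, :5] @ DEFAULT_WEIGHTS.term_weights) / (
            1.0 + DEFAULT_WEIGHTS.w6 * nrot
        )
        return PKD_PER_KCAL * e, {"model": "vina"}
    if cfg.affinity_model == "linear-vina":
        p = X.shape[1]
        coef = rng.normal(scale=1.0, size=p)
        coef[-1] = 0.0  # nrot enters through the rotor penalty only
        coef[X.std(axis=0) == 0] = 0.0  # keep the generator identifiable
        z = (X / (1.0 + cfg.w6_true * nrot)[:, None])
        z[:, -1] = nrot
        y_raw = z @ coef
    elif cfg.affinity_model == "linear-contacts":
        if X.shape[1] < 46:
            raise ValueError("linear-contacts requires the vinaelem47 feature set")
        coef = np.zeros(X.shape[1])
        coef[10:46] = rng.normal(scale=1.0, size=36)
        y_raw = X @ coef
    elif cfg.affinity_model == "nonlinear":
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        z0 = (X[:, 0] - X[:, 0].mean()) / scale[0]
        z2 = (X[:, 2] - X[:, 2].mean()) / scale[2]
        y_raw = np.tanh(z0) + 0.5 * z0 * z2 + 0.3 * np.abs(z2)
        coef = None
    else:
        raise ValueError(f"unknown affinity model {cfg.affinity_model!r}")

    # rescale to the requested pKd span around 5
    span = y_raw.max() - y_raw.min()
    alpha = cfg.affinity_span / span if span > 0 else 1.0
    beta = 5.0 - alpha * float(np.median(y_raw))
    y = alpha * y_raw + beta
    truth = {"model": cfg.affinity_model, "intercept": beta}
    if cfg.affinity_model == "linear-vina":
        truth.update({"w6": cfg.w6_true, "coef": alpha * coef})
    elif cfg.affinity_model == "linear-contacts":
        truth.update({"w6": 0.0, "coef": alpha * coef})
    return y, truth


def make_dataset(cfg: FixtureConfig) -> SyntheticDataset:
    """Generate complexes and affinities with known feature dependence.

    Affinities derive from the features of ``cfg.label_scheme`` (default:
    crystal pose), so models can be trained on docked-pose features while
    the signal lives on crystal features, reproducing the pose-generation
    error setting.
    """
    rng = np.random.default_rng(cfg.seed)
    complexes = [
        make_complex(cfg, rng, complex_id=f"cmpl{i + 1:04d}")
        for i in range(cfg.n_complexes)
    ]
    ds = SyntheticDataset(complexes=complexes, y=np.zeros(cfg.n_complexes), truth={}, config=cfg)
    X_label = ds.feature_matrix(cfg.label_scheme, cfg.feature_set)
    y_clean, truth = _affinity_function(cfg, X_label, rng)
    noise = rng.normal(scale=cfg.noise_sd, size=len(y_clean)) if cfg.noise_sd > 0 else 0.0
    ds.y = y_clean + noise
    truth["noise_sd"] = cfg.noise_sd
    ds.truth = truth
    for (rec, ps), affinity in zip(complexes, ds.y):
        ps.measured_affinity = float(affinity)
    return ds


def write_fixture_tree(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write a PDBbind-like directory tree consumable by every CLI."""
    outdir = Path(outdir)
    rows = []
    for rec, ps in dataset.complexes:
        cdir = outdir / ps.ligand_id
        cdir.mkdir(parents=True, exist_ok=True)
        write_pdbqt(rec, cdir / "receptor.pdbqt")
        write_pdbqt(ps, cdir / "ligand_crystal.pdbqt", which="crystal")
        write_pdbqt(ps, cdir / "ligand_docked.pdbqt", which="docked")
        rows.append({"id": ps.ligand_id, "pKd": ps.measured_affinity})
    pd.DataFrame(rows).to_csv(outdir / "affinities.csv", index=False)
    return outdir


def load_fixture_tree(indir: str | Path) -> list[tuple[Receptor, PoseSet]]:
    """Load a directory tree written by :func:`write_fixture_tree`."""
    indir = Path(indir)
    affinities = {}
    aff_path = indir / "affinities.csv"
    if aff_path.exists():
        df = pd.read_csv(aff_path)
        affinities = dict(zip(df["id"].astype(str), df["pKd"].astype(float)))
    complexes = []
    for cdir in sorted(p for p in indir.iterdir() if p.is_dir()):
        receptor = read_pdbqt(cdir / "receptor.pdbqt", role="receptor")
        docked_path = cdir / "ligand_docked.pdbqt"
        crystal_path = cdir / "ligand_crystal.pdbqt"
        if docked_path.exists():
            ps = read_pdbqt(docked_path, role="ligand", ligand_id=cdir.name)
        else:
            ps = PoseSet(ligand_id=cdir.name)
        if crystal_path.exists():
            cset = read_pdbqt(crystal_path, role="ligand", ligand_id=cdir.name)
            crystal = cset.docked[0]
            crystal.source = "crystal"
            crystal.vina_energy = math.nan
            ps.crystal = crystal
            # crystal geometry is the canonical bond graph (jitter in docked
            # poses can flip distance-detected bonds and hence role flags)
            ps.bonds = cset.bonds
            for pose in ps.all_poses():
                assign_role_flags(pose.atoms, ps.bonds)
            if not ps.docked:
                ps.nrot = cset.nrot
        ps.measured_affinity = affinities.get(cdir.name)
        complexes.append((receptor, ps))
    return complexes
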