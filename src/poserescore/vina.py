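"""AutoDock Vina energy terms, composite score and the pKd conversion.

Five pairwise terms (gauss1, gauss2, repulsion, hydrophobic, hbonding) are
summed over inter-molecular (receptor heavy atom vs ligand heavy atom) and
intra-molecular (movable ligand pairs) atom pairs, each term a function of
the surface distance d = interatomic distance - sum of vdW radii. Pairs
beyond the 8 A interatomic-distance cutoff contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import PoseRecord, PoseSet, Receptor, movable_pairs

__all__ = [
    "TERM_NAMES",
    "VINA_TERM_ORDER",
    "VinaWeights",
    "VinaTermVector",
    "vdw_radius",
    "term_pair",
    "compute_terms",
    "vina_score",
    "score_pose_set",
    "energy_to_pkd",
    "PKD_PER_KCAL",
]

TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbonding")

#: flattening order of the 11-entry Vina feature vector
VINA_TERM_ORDER = tuple(f"{t}_inter" for t in TERM_NAMES) + tuple(
    f"{t}_intra" for t in TERM_NAMES
) + ("nrot",)

#: kcal/mol -> pKd conversion factor
PKD_PER_KCAL = -0.73349480509

#: interaction cutoff on the interatomic distance, Angstrom
CUTOFF = 8.0

# Vina's per-element vdW (xs) radii, Angstrom; metals use the donor-metal radius
_VDW_RADIUS = {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "F": 1.5, "Cl": 1.8, "Br": 2.0, "I": 2.2,
}
_METAL_VDW_RADIUS = 1.2


@dataclass(frozen=True)
class VinaWeights:
    """The six published Vina weights (fixed; never re-fitted here)."""

    w1: float = -0.035579
    w2: float = -0.005156
    w3: float = 0.840245
    w4: float = -0.035069
    w5: float = -0.587439
    w6: float = 0.05846

    @property
    def term_weights(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5])


DEFAULT_WEIGHTS = VinaWeights()


@dataclass
class VinaTermVector:
    """Unweighted term sums for one pose: 5 inter + 5 intra + nrot."""

    inter: np.ndarray  # shape (5,), order TERM_NAMES
    intra: np.ndarray  # shape (5,)
    nrot: int

    def flatten(self) -> np.ndarray:
        """Flatten to 11 entries in :data:`VINA_TERM_ORDER`."""
        return np.concatenate([self.inter, self.intra, [float(self.nrot)]])


def vdw_radius(atom) -> float:
    if atom.is_metal:
        return _METAL_VDW_RADIUS
    try:
        return _VDW_RADIUS[atom.element]
    except KeyError:
        raise ValueError(
            f"no van-der-Waals radius for atom serial {atom.serial} "
            f"(element {atom.element!r})"
        ) from None


def term_pair(
    surface_distance: float,
    hydrophobic_pair: bool = False,
    hbond_pair: bool = False,
) -> np.ndarray:
    """Evaluate the 5 pairwise terms at one surface distance.

    gauss1 = exp(-(d/0.5)^2); gauss2 = exp(-((d-3)/2)^2);
    repulsion = d^2 for d < 0 else 0;
    hydrophobic ramps 1 -> 0 over d in [0.5, 1.5] (hydrophobic pairs only);
    hbonding ramps 1 -> 0 over d in [-0.7, 0] (donor-acceptor pairs only).
    """
    d = float(surface_distance)
    if not np.isfinite(d):
        raise ValueError("surface distance must be finite")
    gauss1 = np.exp(-((d / 0.5) ** 2))
    gauss2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
    repulsion = d * d if d < 0.0 else 0.0
    hydrophobic = 0.0
    if hydrophobic_pair:
        if d <= 0.5:
            hydrophobic = 1.0
        elif d < 1.5:
            hydrophobic = 1.5 - d
    hbonding = 0.0
    if hbond_pair:
        if d <= -0.7:
            hbonding = 1.0
        elif d < 0.0:
            hbonding = d / -0.7
    return np.array([gauss1, gauss2, repulsion, hydrophobic, hbonding])


def _is_hbond_pair(a, b) -> bool:
    return (a.is_hbond_donor and b.is_hbond_acceptor) or (
        b.is_hbond_donor and a.is_hbond_acceptor
    )


def _pair_terms(a, b, distance: float) -> np.ndarray:
    d = distance - vdw_radius(a) - vdw_radius(b)
    return term_pair(
        d,
        hydrophobic_pair=a.is_hydrophobic and b.is_hydrophobic,
        hbond_pair=_is_hbond_pair(a, b),
    )


def compute_terms(
    receptor: Receptor,
    pose: PoseRecord,
    nrot: int,
    intra_pairs: list[tuple[int, int]] | None = None,
) -> VinaTermVector:
    """Sum the 5 terms over inter and intra heavy-atom pairs for one pose.

    ``intra_pairs`` are index pairs (into ``pose.atoms``) of ligand atoms
    that can move relative to each other; ``None`` or empty means a rigid
    ligand, for which all intra terms are zero.
    """
    rec_atoms = receptor.heavy_atoms()
    lig_atoms = pose.heavy_atoms()

    inter = np.zeros(5)
    if rec_atoms and lig_atoms:
        rc = np.array([a.coords for a in rec_atoms])
        lc = np.array([a.coords for a in lig_atoms])
        dists = np.linalg.norm(rc[:, None, :] - lc[None, :, :], axis=2)
        for i, j in zip(*np.nonzero(dists <= CUTOFF)):
            inter += _pair_terms(rec_atoms[i], lig_atoms[j], dists[i, j])

    intra = np.zeros(5)
    for i, j in intra_pairs or []:
        a, b = pose.atoms[i], pose.atoms[j]
        if not (a.is_heavy and b.is_heavy):
            continue
        dist = float(np.linalg.norm(a.coords - b.coords))
        if dist <= CUTOFF:
            intra += _pair_terms(a, b, dist)

    return VinaTermVector(inter=inter, intra=intra, nrot=int(nrot))


def weighted_energy(term_block: np.ndarray, weights: VinaWeights = DEFAULT_WEIGHTS) -> float:
    """w1..w5 dotted with one 5-term block (kcal/mol)."""
    return float(np.dot(weights.term_weights, term_block))


def vina_score(
    terms: VinaTermVector,
    intra_energy_pose1: float,
    weights: VinaWeights = DEFAULT_WEIGHTS,
) -> float:
    """Composite Vina score of one pose, kcal/mol.

    score = (e_inter + e_intra - e_intra_of_rank1_pose) / (1 + w6 * nrot).
    For the rank-1 pose itself the intra contributions cancel exactly.
    """
    e_inter = weighted_energy(terms.inter, weights)
    e_intra = weighted_energy(terms.intra, weights)
    return (e_inter + e_intra - intra_energy_pose1) / (1.0 + weights.w6 * terms.nrot)


def score_pose_set(
    receptor: Receptor,
    pose_set: PoseSet,
    weights: VinaWeights = DEFAULT_WEIGHTS,
    poses: list[PoseRecord] | None = None,
) -> list[float]:
    """Vina scores (kcal/mol) for the given poses of one ligand.

    The intra reference is the rank-1 (lowest-energy) docked pose when
    docked poses exist, else the pose itself (crystal-only scoring, where
    the intra contributions cancel).
    """
    if poses is None:
        poses = pose_set.docked if pose_set.docked else [pose_set.reference_pose()]
    pairs = movable_pairs(pose_set)
    if pose_set.docked:
        ref_terms = compute_terms(receptor, pose_set.docked[0], pose_set.nrot, pairs)
        intra1 = weighted_energy(ref_terms.intra, weights)
    else:
        intra1 = None
    scores = []
    for pose in poses:
        t = compute_terms(receptor, pose, pose_set.nrot, pairs)
        ref = weighted_energy(t.intra, weights) if intra1 is None else intra1
        scores.append(vina_score(t, ref, weights))
    return scores


def energy_to_pkd(e: float) -> float:
    """Convert a predicted free energy (kcal/mol) to pKd units."""
    if not np.isfinite(e):
        raise ValueError("energy must be finite")
    return PKD_PER_KCAL * e
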