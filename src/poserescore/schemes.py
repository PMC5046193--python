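"""Pose-selection schemes 1-6 and model-ready feature assembly.

Scheme 1 uses the crystal pose; 2 the best-scored docked pose; 3 the
docked pose with lowest RMSD vs crystal (training only); 4 the docked pose
whose converted Vina score is closest to the measured affinity (training
only); 5 all nine docked poses; 6 the two best-scored docked poses.

The pose-dependent feature block is the 10 Vina term sums (5 inter + 5
intra), optionally followed by the 36 elemental contact counts; the
rotatable-bond count is pose-invariant and appended exactly once, giving
vector lengths 11/47 (single pose), 21/93 (scheme 6) and 91/415 (scheme 5).
Short pose lists are padded by repeating the best-scored pose's block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import DEFAULT_CUTOFF, contact_feature_names, count_contacts
from .metrics import rmsd
from .structures import PoseRecord, PoseSet, Receptor, movable_pairs
from .vina import TERM_NAMES, compute_terms, energy_to_pkd, score_pose_set

__all__ = [
    "SchemeSpec",
    "FeatureVector",
    "BLOCK_SIZES",
    "POSES_PER_SCHEME",
    "feature_length",
    "feature_names",
    "select_pose",
    "assemble_features",
]

FEATURE_SETS = ("vina11", "vinaelem47")

#: pose-dependent block size per feature set (nrot excluded)
BLOCK_SIZES = {"vina11": 10, "vinaelem47": 46}

#: number of pose blocks per scheme
POSES_PER_SCHEME = {1: 1, 2: 1, 3: 1, 4: 1, 5: 9, 6: 2}

TRAIN_ONLY_SCHEMES = (3, 4)


@dataclass(frozen=True)
class SchemeSpec:
    scheme_id: int
    feature_set: str = "vina11"

    def __post_init__(self) -> None:
        if self.scheme_id not in POSES_PER_SCHEME:
            raise ValueError(f"unknown scheme {self.scheme_id}; expected 1-6")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature set {self.feature_set!r}; expected one of {FEATURE_SETS}"
            )

    @property
    def n_pose_blocks(self) -> int:
        return POSES_PER_SCHEME[self.scheme_id]

    @property
    def length(self) -> int:
        return self.n_pose_blocks * BLOCK_SIZES[self.feature_set] + 1


def feature_length(scheme_id: int, feature_set: str) -> int:
    """Total feature-vector length for a scheme/feature-set combination."""
    return SchemeSpec(scheme_id, feature_set).length


@dataclass
class FeatureVector:
    values: np.ndarray
    complex_id: str
    scheme: SchemeSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.scheme.length,):
            raise ValueError(
                f"{self.complex_id}: expected {self.scheme.length} features "
                f"for scheme {self.scheme.scheme_id}/{self.scheme.feature_set}, "
                f"got {self.values.shape}"
            )


def _block_names(feature_set: str) -> list[str]:
    names = [f"{t}_inter" for t in TERM_NAMES] + [f"{t}_intra" for t in TERM_NAMES]
    if feature_set == "vinaelem47":
        names += contact_feature_names()
    return names


def feature_names(spec: SchemeSpec) -> list[str]:
    """Column names matching :func:`assemble_features` output order."""
    block = _block_names(spec.feature_set)
    if spec.n_pose_blocks == 1:
        names = list(block)
    else:
        names = [f"p{k}_{n}" for k in range(1, spec.n_pose_blocks + 1) for n in block]
    return names + ["nrot"]


def select_pose(
    poses: PoseSet,
    scheme_id: int,
    crystal_ref: PoseRecord | None = None,
    vina_scores: list[float] | None = None,
) -> PoseRecord:
    """Pick the single pose that represents the ligand under schemes 1-4.

    ``vina_scores`` (kcal/mol, aligned with ``poses.docked``) is required
    for scheme 4; scheme 2 uses the stored per-pose energies. Ties are
    broken by lowest rank.
    """
    if scheme_id == 1:
        if poses.crystal is None:
            raise ValueError(f"scheme 1 requires a crystal pose ({poses.ligand_id})")
        return poses.crystal
    if not poses.docked:
        raise ValueError(f"scheme {scheme_id} requires docked poses ({poses.ligand_id})")
    if scheme_id == 2:
        return min(poses.docked, key=lambda p: (p.vina_energy, p.rank))
    if scheme_id == 3:
        ref = crystal_ref or poses.crystal
        if ref is None:
            raise ValueError(f"scheme 3 requires a crystal reference ({poses.ligand_id})")
        return min(poses.docked, key=lambda p: (rmsd(ref, p), p.rank))
    if scheme_id == 4:
        if poses.measured_affinity is None:
            raise ValueError(f"scheme 4 requires a measured affinity ({poses.ligand_id})")
        if vina_scores is None or len(vina_scores) != len(poses.docked):
            raise ValueError("scheme 4 requires a vina score per docked pose")
        y = poses.measured_affinity
        best = min(
            zip(poses.docked, vina_scores),
            key=lambda pe: (abs(energy_to_pkd(pe[1]) - y), pe[0].rank),
        )
        return best[0]
    raise ValueError(f"scheme {scheme_id} does not select a single pose")


def _pose_block(
    receptor: Receptor,
    pose: PoseRecord,
    pose_set: PoseSet,
    feature_set: str,
    intra_pairs,
    d_cutoff: float,
) -> np.ndarray:
    terms = compute_terms(receptor, pose, pose_set.nrot, intra_pairs)
    block = np.concatenate([terms.inter, terms.intra])
    if feature_set == "vinaelem47":
        block = np.concatenate([block, count_contacts(receptor, pose, d_cutoff)])
    return block


def assemble_features(
    poses: PoseSet,
    spec: SchemeSpec,
    receptor: Receptor,
    d_cutoff: float = DEFAULT_CUTOFF,
) -> FeatureVector:
    """Build the model-ready feature vector for one complex under a scheme.

    Multi-pose schemes concatenate per-pose blocks in ascending Vina-energy
    order; missing poses are padded with the best-scored pose's block.
    """
    intra_pairs = movable_pairs(poses)

    if spec.scheme_id in (1, 2, 3, 4):
        vina_scores = None
        if spec.scheme_id == 4:
            vina_scores = score_pose_set(receptor, poses)
        pose = select_pose(poses, spec.scheme_id, vina_scores=vina_scores)
        blocks = [_pose_block(receptor, pose, poses, spec.feature_set, intra_pairs, d_cutoff)]
    else:
        if not poses.docked:
            raise ValueError(
                f"scheme {spec.scheme_id} requires docked poses ({poses.ligand_id})"
            )
        m = spec.n_pose_blocks
        ordered = sorted(poses.docked, key=lambda p: (p.vina_energy, p.rank))[:m]
        blocks = [
            _pose_block(receptor, p, poses, spec.feature_set, intra_pairs, d_cutoff)
            for p in ordered
        ]
        while len(blocks) < m:  # pad with the best-scored pose's block
            blocks.append(blocks[0].copy())

    values = np.concatenate(blocks + [np.array([float(poses.nrot)])])
    return FeatureVector(values=values, complex_id=poses.ligand_id, scheme=spec)
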