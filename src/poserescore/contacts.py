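"""Elemental occurrence-count contact features.

36 integer counts of (ligand element, protein element) heavy-atom pairs
within ``d_cutoff`` Angstrom, laid out row-major over 9 ligand elements x 4
protein elements. Hydrogens, metals and any element outside the supported
sets are excluded from counting.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .structures import PoseRecord, Receptor

__all__ = [
    "LIGAND_ELEMENTS",
    "PROTEIN_ELEMENTS",
    "N_CONTACT_FEATURES",
    "contact_feature_names",
    "count_contacts",
]

LIGAND_ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
PROTEIN_ELEMENTS = ("C", "N", "O", "S")
N_CONTACT_FEATURES = len(LIGAND_ELEMENTS) * len(PROTEIN_ELEMENTS)  # 36

DEFAULT_CUTOFF = 12.0

_LIG_INDEX = {e: i for i, e in enumerate(LIGAND_ELEMENTS)}
_PROT_INDEX = {e: j for j, e in enumerate(PROTEIN_ELEMENTS)}


def contact_feature_names() -> list[str]:
    """Column names ``x_<LigElem>_<ProtElem>`` in flattening order."""
    return [f"x_{li}_{pj}" for li in LIGAND_ELEMENTS for pj in PROTEIN_ELEMENTS]


def count_contacts(
    receptor: Receptor,
    pose: PoseRecord,
    d_cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Count cross pairs with distance <= ``d_cutoff`` per element pair.

    The boundary counts as inside (Heaviside with H(0) = 1). Returns a
    length-36 integer vector, row-major over ligand x protein elements.
    """
    if d_cutoff <= 0:
        raise ValueError(f"d_cutoff must be positive, got {d_cutoff}")
    lig = [a for a in pose.atoms if a.is_heavy and a.element in _LIG_INDEX]
    prot = [a for a in receptor.atoms if a.is_heavy and a.element in _PROT_INDEX]
    x = np.zeros((len(LIGAND_ELEMENTS), len(PROTEIN_ELEMENTS)), dtype=np.int64)
    if lig and prot:
        lc = np.array([a.coords for a in lig])
        pc = np.array([a.coords for a in prot])
        within = cdist(lc, pc) <= d_cutoff
        li = np.array([_LIG_INDEX[a.element] for a in lig])
        pj = np.array([_PROT_INDEX[a.element] for a in prot])
        for l, p in zip(*np.nonzero(within)):
            x[li[l], pj[p]] += 1
    return x.ravel()
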