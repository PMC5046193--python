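import numpy as np
import pytest

from poserescore.structures import (
    PoseRecord,
    PoseSet,
    Receptor,
    TypedAtom,
    assign_role_flags,
    detect_bonds,
)
from poserescore.synthetic import FixtureConfig, make_complex, make_dataset


def atom(serial, x, y, z, element="C", ad_type=None, **kw):
    """Shorthand TypedAtom constructor for tests."""
    return TypedAtom(
        serial=serial,
        name=f"{element}{serial}",
        coords=np.array([x, y, z], dtype=float),
        element=element,
        ad_type=ad_type or element.upper(),
        **kw,
    )


@pytest.fixture(scope="session")
def nine_pose_complex():
    """One synthetic complex with exactly 9 docked poses."""
    cfg = FixtureConfig(n_poses=9, seed=11)
    return make_complex(cfg, np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_linear_dataset():
    """Noise-free linear-in-Vina-terms dataset (labels from scheme 2)."""
    cfg = FixtureConfig(
        n_complexes=60,
        seed=7,
        affinity_model="linear-vina",
        noise_sd=0.0,
        label_scheme=2,
        feature_set="vina11",
    )
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def small_tree(tmp_path_factory):
    """A written fixture tree with 6 complexes."""
    from poserescore.synthetic import write_fixture_tree

    cfg = FixtureConfig(n_complexes=6, seed=3, noise_sd=0.2)
    ds = make_dataset(cfg)
    out = tmp_path_factory.mktemp("tree") / "complexes"
    write_fixture_tree(ds, out)
    return out, ds


def single_atom_pose(x, y, z, element="C", **kw):
    return PoseRecord(atoms=[atom(1, x, y, z, element, **kw)], rank=1)


def make_receptor(atoms):
    bonds = detect_bonds(atoms)
    assign_role_flags(atoms, bonds)
    return Receptor(id="rec", atoms=atoms)
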