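import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poserescore.structures import PoseRecord, Receptor, movable_pairs
from poserescore.vina import (
    CUTOFF,
    DEFAULT_WEIGHTS,
    PKD_PER_KCAL,
    VinaTermVector,
    compute_terms,
    energy_to_pkd,
    score_pose_set,
    term_pair,
    vdw_radius,
    vina_score,
    weighted_energy,
)

from .conftest import atom, make_receptor

R_CC = 1.9 + 1.9  # carbon-carbon vdW radii sum


class TestTermPair:
    def test_d_zero_hydrophobic_carbon_pair(self):
        g1, g2, rep, hyd, hb = term_pair(0.0, hydrophobic_pair=True)
        assert g1 == pytest.approx(1.0)
        assert g2 == pytest.approx(math.exp(-2.25))
        assert rep == 0.0
        assert hyd == 1.0
        assert hb == 0.0

    def test_d_three_no_roles(self):
        g1, g2, rep, hyd, hb = term_pair(3.0)
        assert g2 == pytest.approx(1.0)
        assert g1 == pytest.approx(math.exp(-36.0))
        assert (rep, hyd, hb) == (0.0, 0.0, 0.0)

    def test_d_minus_07_donor_acceptor(self):
        g1, g2, rep, hyd, hb = term_pair(-0.7, hbond_pair=True)
        assert hb == pytest.approx(1.0)
        assert rep == pytest.approx(0.49)

    def test_hbond_ramp_midpoint(self):
        *_, hb = term_pair(-0.35, hbond_pair=True)
        assert hb == pytest.approx(0.5)

    def test_hydrophobic_ramp(self):
        assert term_pair(1.5, hydrophobic_pair=True)[3] == 0.0
        assert term_pair(1.0, hydrophobic_pair=True)[3] == pytest.approx(0.5)

    def test_hydrophobic_monotone_from_15_to_05(self):
        values = [term_pair(d, hydrophobic_pair=True)[3] for d in np.linspace(1.5, 0.5, 50)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            term_pair(float("nan"))


class TestComputeTerms:
    def test_single_pair_surface_contact(self):
        rec = make_receptor([atom(1, 0, 0, 0)])
        pose = PoseRecord(atoms=[atom(1, R_CC, 0, 0)])
        pose.atoms[0].is_hydrophobic = True
        t = compute_terms(rec, pose, nrot=0)
        assert t.inter[0] == pytest.approx(1.0)  # gauss1
        assert t.inter[2] == 0.0  # repulsion
        np.testing.assert_array_equal(t.intra, np.zeros(5))

    def test_rigid_ligand_no_intra(self, nine_pose_complex):
        rec, ps = nine_pose_complex
        t = compute_terms(rec, ps.docked[0], nrot=0, intra_pairs=[])
        np.testing.assert_array_equal(t.intra, np.zeros(5))

    def test_beyond_cutoff_all_zero(self):
        rec = make_receptor([atom(1, 0, 0, 0)])
        pose = PoseRecord(atoms=[atom(1, 9.0 + R_CC, 0, 0)])
        t = compute_terms(rec, pose, nrot=0)
        np.testing.assert_array_equal(t.inter, np.zeros(5))

    def test_flatten_layout(self):
        t = VinaTermVector(inter=np.arange(5.0), intra=np.arange(5.0, 10.0), nrot=7)
        flat = t.flatten()
        assert flat.shape == (11,)
        assert flat[-1] == 7.0

    def test_unknown_radius_named(self):
        rec = make_receptor([atom(1, 0, 0, 0)])
        bad = atom(1, 2, 0, 0, element="Xx", ad_type="C")
        bad.element = "Xx"
        with pytest.raises(ValueError, match="serial 1"):
            compute_terms(rec, PoseRecord(atoms=[bad]), nrot=0)


def brute_force_terms(receptor, pose, intra_pairs):
    """Independent double-loop oracle for the inter/intra term sums."""
    inter = np.zeros(5)
    for ra in receptor.atoms:
        if not ra.is_heavy:
            continue
        for la in pose.atoms:
            if not la.is_heavy:
                continue
            dist = math.dist(ra.coords, la.coords)
            if dist > CUTOFF:
                continue
            d = dist - vdw_radius(ra) - vdw_radius(la)
            hydro = ra.is_hydrophobic and la.is_hydrophobic
            hb = (ra.is_hbond_donor and la.is_hbond_acceptor) or (
                la.is_hbond_donor and ra.is_hbond_acceptor
            )
            inter += term_pair(d, hydro, hb)
    intra = np.zeros(5)
    for i, j in intra_pairs:
        a, b = pose.atoms[i], pose.atoms[j]
        if not (a.is_heavy and b.is_heavy):
            continue
        dist = math.dist(a.coords, b.coords)
        if dist > CUTOFF:
            continue
        d = dist - vdw_radius(a) - vdw_radius(b)
        hydro = a.is_hydrophobic and b.is_hydrophobic
        hb = (a.is_hbond_donor and b.is_hbond_acceptor) or (
            b.is_hbond_donor and a.is_hbond_acceptor
        )
        intra += term_pair(d, hydro, hb)
    return inter, intra


class TestOracleEquivalence:
    def test_pair_sum_matches_brute_force(self, nine_pose_complex):
        rec, ps = nine_pose_complex
        pairs = movable_pairs(ps)
        for pose in [ps.crystal] + ps.docked[:3]:
            t = compute_terms(rec, pose, ps.nrot, pairs)
            inter, intra = brute_force_terms(rec, pose, pairs)
            np.testing.assert_allclose(t.inter, inter, rtol=0, atol=1e-12)
            np.testing.assert_allclose(t.intra, intra, rtol=0, atol=1e-12)

    def test_rigid_motion_invariance(self, nine_pose_complex):
        rec, ps = nine_pose_complex
        pairs = movable_pairs(ps)
        pose = ps.docked[0]
        base = compute_terms(rec, pose, ps.nrot, pairs)

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        shift = np.array([5.0, -2.0, 9.0])

        def moved(atoms):
            out = []
            for a in atoms:
                b = atom(a.serial, *(rot.apply(a.coords) + shift), element=a.element,
                         ad_type=a.ad_type)
                b.is_hydrophobic = a.is_hydrophobic
                b.is_hbond_donor = a.is_hbond_donor
                b.is_hbond_acceptor = a.is_hbond_acceptor
                out.append(b)
            return out

        rec2 = Receptor(id="moved", atoms=moved(rec.atoms))
        pose2 = PoseRecord(atoms=moved(pose.atoms))
        t2 = compute_terms(rec2, pose2, ps.nrot, pairs)
        np.testing.assert_allclose(t2.inter, base.inter, atol=1e-9)
        np.testing.assert_allclose(t2.intra, base.intra, atol=1e-9)


class TestVinaScore:
    def test_zero_terms_score_zero(self):
        t = VinaTermVector(inter=np.zeros(5), intra=np.zeros(5), nrot=4)
        assert vina_score(t, 0.0) == 0.0

    def test_unit_denominator(self):
        # e_inter = -5 via repulsion channel scaled to give -5 exactly
        inter = np.array([0.0, 0.0, 0.0, 0.0, -5.0 / DEFAULT_WEIGHTS.w5])
        t = VinaTermVector(inter=inter, intra=np.zeros(5), nrot=0)
        assert vina_score(t, 0.0) == pytest.approx(-5.0)

    def test_rank1_intra_cancellation(self, nine_pose_complex):
        rec, ps = nine_pose_complex
        pairs = movable_pairs(ps)
        t1 = compute_terms(rec, ps.docked[0], ps.nrot, pairs)
        intra1 = weighted_energy(t1.intra)
        score = vina_score(t1, intra1)
        expected = weighted_energy(t1.inter) / (1 + DEFAULT_WEIGHTS.w6 * ps.nrot)
        assert score == pytest.approx(expected, abs=1e-12)

    def test_score_pose_set_orders_consistently(self, nine_pose_complex):
        rec, ps = nine_pose_complex
        scores = score_pose_set(rec, ps)
        assert len(scores) == len(ps.docked)
        np.testing.assert_allclose(
            scores, [p.vina_energy for p in ps.docked], atol=1e-9
        )


class TestEnergyToPkd:
    def test_zero(self):
        assert energy_to_pkd(0.0) == 0.0

    def test_minus_one(self):
        assert energy_to_pkd(-1.0) == pytest.approx(0.73349480509, abs=0)

    def test_minus_ten_linearity(self):
        assert energy_to_pkd(-10.0) == pytest.approx(7.3349480509, abs=1e-12)

    def test_constant(self):
        assert PKD_PER_KCAL == -0.73349480509


class TestWeights:
    def test_published_defaults(self):
        w = DEFAULT_WEIGHTS
        assert (w.w1, w.w2, w.w3, w.w4, w.w5, w.w6) == (
            -0.035579,
            -0.005156,
            0.840245,
            -0.035069,
            -0.587439,
            0.05846,
        )
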