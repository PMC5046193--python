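import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from poserescore.metrics import (
    EvalReport,
    error_rmsd_correlation,
    evaluate,
    rmsd,
    rmse,
    rp,
    rs,
    sd,
    success_rates,
)
from poserescore.structures import PoseRecord

from .conftest import atom


def pose_from_coords(coords):
    return PoseRecord(atoms=[atom(i + 1, *xyz) for i, xyz in enumerate(coords)])


class TestRmse:
    def test_identical(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_alternating_unit_errors(self):
        y = np.array([0.0, 0.0, 0.0, 0.0])
        p = y + np.array([1.0, -1.0, 1.0, -1.0])
        assert rmse(p, y) == pytest.approx(1.0)

    def test_single_pair(self):
        assert rmse([5.0], [7.0]) == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])


def sd_oracle(pred, meas):
    """Closed-form simple-regression residual SD (independent route)."""
    res = scipy.stats.linregress(pred, meas)
    fitted = res.intercept + res.slope * np.asarray(pred)
    resid = np.asarray(meas) - fitted
    return float(np.sqrt(np.sum(resid**2) / (len(pred) - 2)))


class TestSd:
    def test_collinear_zero(self):
        assert sd([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle(self):
        y = [1.0, 2.0, 3.0, 4.0]
        p = [1.1, 1.9, 3.2, 3.8]
        assert sd(p, y) == pytest.approx(sd_oracle(p, y), abs=1e-10)

    def test_leverage_case_matches_oracle(self):
        y = [0.0, 1.0, 2.0]
        p = [0.0, 1.0, 100.0]
        assert sd(p, y) == pytest.approx(sd_oracle(p, y), abs=1e-10)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            sd([1, 2], [1, 2])

    def test_zero_variance_pred(self):
        with pytest.raises(ValueError):
            sd([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100),
                st.floats(-100, 100),
            ),
            min_size=4,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_property_matches_oracle(self, pairs):
        p = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        if np.var(p) < 1e-9:
            return
        assert sd(p, y) == pytest.approx(sd_oracle(p, y), abs=1e-8)


class TestCorrelations:
    def test_affine_increasing(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = 2 * y + 1
        assert rp(p, y) == pytest.approx(1.0)
        assert rs(p, y) == pytest.approx(1.0)

    def test_negation(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rp(-y, y) == pytest.approx(-1.0)

    def test_spearman_hand_case(self):
        meas = [1, 2, 3, 4, 5]
        pred = [1, 3, 2, 4, 5]
        assert rs(pred, meas) == pytest.approx(0.9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        p = rng.normal(size=40)
        y = 0.5 * p + rng.normal(size=40)
        assert rp(p, y) == pytest.approx(scipy.stats.pearsonr(p, y).statistic, abs=1e-12)
        assert rs(p, y) == pytest.approx(scipy.stats.spearmanr(p, y).statistic, abs=1e-12)

    def test_ties_use_average_ranks(self):
        p = [1.0, 1.0, 2.0, 3.0]
        y = [4.0, 5.0, 6.0, 7.0]
        assert rs(p, y) == pytest.approx(scipy.stats.spearmanr(p, y).statistic, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rp([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_rs_invariant_under_monotone_transform(self, values, transform):
        rng = np.random.default_rng(abs(hash(tuple(values))) % (2**32))
        y = rng.permutation(len(values)).astype(float)
        p = np.array(values, dtype=float)
        if np.var(y) == 0 or np.var(p) == 0:
            return
        f = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3 * v + 2}[transform]
        transformed = f(p / 10.0)
        assert rs(transformed, y) == pytest.approx(rs(p, y), abs=1e-10)


class TestRmsd:
    def test_identical(self):
        pose = pose_from_coords([(0, 0, 0), (1, 1, 1)])
        assert rmsd(pose, pose) == 0.0

    def test_translation(self):
        a = pose_from_coords([(0, 0, 0), (1, 0, 0), (0, 2, 0)])
        b = pose_from_coords([(3, 4, 0), (4, 4, 0), (3, 6, 0)])
        assert rmsd(a, b) == pytest.approx(5.0)

    def test_two_atom_mixed(self):
        a = pose_from_coords([(0, 0, 0), (1, 0, 0)])
        b = pose_from_coords([(0, 0, 0), (3, 0, 0)])
        assert rmsd(a, b) == pytest.approx(np.sqrt(2.0))

    def test_count_mismatch(self):
        a = pose_from_coords([(0, 0, 0)])
        b = pose_from_coords([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(ValueError, match="mismatch"):
            rmsd(a, b)

    def test_hydrogens_ignored(self):
        a = PoseRecord(atoms=[atom(1, 0, 0, 0), atom(2, 1, 0, 0, element="H", ad_type="HD")])
        b = PoseRecord(atoms=[atom(1, 2, 0, 0), atom(2, 9, 9, 9, element="H", ad_type="HD")])
        assert rmsd(a, b) == pytest.approx(2.0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pts = rng.normal(size=(3, 5, 3)) * 3
            a, b, c = (pose_from_coords(p) for p in pts)
            assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12


class TestSuccessRates:
    def test_exhaustive_counts(self):
        data = [
            [1.5, 3.0],  # best pose succeeds
            [2.5, 1.0],  # only a later pose succeeds
            [4.0, 5.0],  # no success
            [2.0, 2.0],  # exactly at threshold -> NOT a success (strict)
        ]
        best, any_ = success_rates(data, threshold=2.0)
        assert best == pytest.approx(1 / 4)
        assert any_ == pytest.approx(2 / 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            success_rates([])


class TestErrorRmsdCorrelation:
    def _report(self, errors, rmsds):
        per = [
            {"id": str(i), "measured": 0.0, "predicted": e, "abs_error": e,
             "rmsd_of_scored_pose": r}
            for i, (e, r) in enumerate(zip(errors, rmsds))
        ]
        return EvalReport(rmse=0, sd=0, rp=0, rs=0, per_complex=per)

    def test_identity_gives_rp_one(self):
        vals = [0.5, 1.0, 2.0, 3.0]
        pearson, spearman = error_rmsd_correlation(self._report(vals, vals))
        assert pearson == pytest.approx(1.0)
        assert spearman == pytest.approx(1.0)

    def test_constant_errors_rejected(self):
        with pytest.raises(ValueError):
            error_rmsd_correlation(self._report([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_independent_null_is_near_zero(self):
        rng = np.random.default_rng(123)
        errors = rng.exponential(size=1000)
        rmsds = rng.exponential(size=1000)
        pearson, _ = error_rmsd_correlation(self._report(errors, rmsds))
        assert abs(pearson) < 0.1

    def test_too_few(self):
        with pytest.raises(ValueError):
            error_rmsd_correlation(self._report([1.0, 2.0], [1.0, 2.0]))


class TestEvaluate:
    def test_report_fields(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5, 1.5, size=20)
        p = y + rng.normal(0, 0.5, size=20)
        ids = [f"c{i}" for i in range(20)]
        report = evaluate(ids, p, y, scored_pose_rmsds=np.abs(rng.normal(size=20)))
        assert report.rmse >= 0 and report.sd >= 0
        assert -1 <= report.rp <= 1 and -1 <= report.rs <= 1
        assert len(report.per_complex) == 20
        assert report.per_complex[0]["id"] == "c0"
        d = report.to_dict()
        assert set(d) == {"rmse", "sd", "rp", "rs", "per_complex"}
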