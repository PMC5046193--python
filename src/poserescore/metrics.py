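"""Evaluation metrics: RMSE, SD, Pearson/Spearman correlation, pose RMSD.

All affinity metrics are implemented from their product-moment /
residual-sum closed forms (the test suite checks them against independent
scipy/statistics oracles). RMSD is the plain heavy-atom coordinate RMSD of
docking convention: no superposition, no symmetry correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .structures import PoseRecord, PoseSet

__all__ = [
    "rmse",
    "sd",
    "rp",
    "rs",
    "rmsd",
    "pose_rmsds",
    "success_rates",
    "error_rmsd_correlation",
    "EvalReport",
    "evaluate",
    "SUCCESS_RMSD_THRESHOLD",
]

#: commonly accepted redocking success threshold, Angstrom (strict <)
SUCCESS_RMSD_THRESHOLD = 2.0


def _check_pair(pred, meas) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    y = np.asarray(meas, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs measured {y.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return p, y


def rmse(pred, meas) -> float:
    """Root mean squared error (no linear fit involved)."""
    p, y = _check_pair(pred, meas)
    return float(np.sqrt(np.mean((p - y) ** 2)))


def sd(pred, meas) -> float:
    """Residual standard deviation of the regression of measured on predicted.

    Fits y = a + b*p by ordinary least squares and returns
    sqrt(sum((fitted - y)^2) / (N - 2)).
    """
    p, y = _check_pair(pred, meas)
    n = p.size
    if n < 3:
        raise ValueError(f"SD requires at least 3 points, got {n}")
    var_p = np.sum((p - p.mean()) ** 2)
    if var_p == 0:
        raise ValueError("SD undefined: predicted values have zero variance")
    b = np.sum((p - p.mean()) * (y - y.mean())) / var_p
    a = y.mean() - b * p.mean()
    fitted = a + b * p
    return float(np.sqrt(np.sum((fitted - y) ** 2) / (n - 2)))


def rp(pred, meas) -> float:
    """Pearson product-moment correlation."""
    p, y = _check_pair(pred, meas)
    n = p.size
    if n < 2:
        raise ValueError("correlation requires at least 2 points")
    num = n * np.sum(p * y) - np.sum(p) * np.sum(y)
    den = np.sqrt(
        (n * np.sum(p**2) - np.sum(p) ** 2) * (n * np.sum(y**2) - np.sum(y) ** 2)
    )
    if den == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(num / den)


def rs(pred, meas) -> float:
    """Spearman rank correlation: Pearson on average (mid) ranks."""
    p, y = _check_pair(pred, meas)
    return rp(rankdata(p), rankdata(y))


def rmsd(pose_a: PoseRecord, pose_b: PoseRecord) -> float:
    """Heavy-atom coordinate RMSD between two poses of the same ligand.

    Atoms correspond by order; no superposition or symmetry-equivalent atom
    relabeling is applied.
    """
    ca = pose_a.coords(heavy_only=True)
    cb = pose_b.coords(heavy_only=True)
    if ca.shape != cb.shape:
        raise ValueError(
            f"heavy-atom count mismatch: {ca.shape[0]} vs {cb.shape[0]}"
        )
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def pose_rmsds(pose_set: PoseSet) -> list[float]:
    """RMSD of every docked pose against the crystal pose."""
    if pose_set.crystal is None:
        raise ValueError(f"pose set {pose_set.ligand_id!r} has no crystal pose")
    return [rmsd(pose_set.crystal, p) for p in pose_set.docked]


def success_rates(
    rmsds_per_ligand: list[list[float]],
    threshold: float = SUCCESS_RMSD_THRESHOLD,
) -> tuple[float, float]:
    """Redocking success rates over ligands: (best-pose rate, any-pose rate).

    ``rmsds_per_ligand[i]`` lists the docked-pose RMSDs of ligand i in rank
    order; success means RMSD strictly below ``threshold``.
    """
    if not rmsds_per_ligand:
        raise ValueError("no ligands given")
    best = sum(1 for r in rmsds_per_ligand if r and r[0] < threshold)
    any_ = sum(1 for r in rmsds_per_ligand if r and min(r) < threshold)
    n = len(rmsds_per_ligand)
    return best / n, any_ / n


@dataclass
class EvalReport:
    """Aggregate metrics plus per-complex errors for correlation analysis."""

    rmse: float
    sd: float
    rp: float
    rs: float
    per_complex: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "sd": self.sd,
            "rp": self.rp,
            "rs": self.rs,
            "per_complex": self.per_complex,
        }


def evaluate(
    ids,
    predicted,
    measured,
    scored_pose_rmsds=None,
) -> EvalReport:
    """Build an :class:`EvalReport` from per-complex predictions."""
    p, y = _check_pair(predicted, measured)
    ids = list(ids)
    if len(ids) != p.size:
        raise ValueError("ids length mismatch")
    rmsds = list(scored_pose_rmsds) if scored_pose_rmsds is not None else [None] * p.size
    per_complex = [
        {
            "id": i,
            "measured": float(yy),
            "predicted": float(pp),
            "abs_error": float(abs(pp - yy)),
            "rmsd_of_scored_pose": (None if r is None else float(r)),
        }
        for i, pp, yy, r in zip(ids, p, y, rmsds)
    ]
    return EvalReport(
        rmse=rmse(p, y), sd=sd(p, y), rp=rp(p, y), rs=rs(p, y), per_complex=per_complex
    )


def error_rmsd_correlation(report: EvalReport) -> tuple[float, float]:
    """Correlate per-complex pose RMSD with absolute prediction error.

    Returns (Pearson, Spearman) over complexes with a recorded RMSD.
    """
    rows = [c for c in report.per_complex if c["rmsd_of_scored_pose"] is not None]
    if len(rows) < 3:
        raise ValueError("need at least 3 complexes with pose RMSDs")
    errs = [c["abs_error"] for c in rows]
    rmsds = [c["rmsd_of_scored_pose"] for c in rows]
    return rp(rmsds, errs), rs(rmsds, errs)
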