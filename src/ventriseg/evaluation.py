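"""Segmentation quality metrics and suite-level aggregation.

Per case: Dice overlap, voxel sensitivity/specificity (negatives restricted to
a domain mask, by default the brain), and the one-directional boundary RMSE in
mm (each predicted boundary point matched to the closest reference boundary
point in the same slice).  Per suite: mean/SD/min/max tables, the reliability
curve R(d) = fraction of cases with Dice strictly greater than d, and the
Pearson correlation between predicted and reference volumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import BinaryVolume, check_same_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "SuiteSummary",
    "dice",
    "sensitivity_specificity",
    "boundary_rmse",
    "reliability",
    "volume_correlation",
    "evaluate_case",
    "summarize_suite",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def dice(seg: BinaryVolume, ref: BinaryVolume) -> float:
    """Dice overlap 2|S n R| / (|S| + |R|); two empty masks count as 1."""
    check_same_geometry(seg, ref)
    s, r = seg.mask, ref.mask
    denom = int(s.sum()) + int(r.sum())
    if denom == 0:
        logger.warning("both masks empty; Dice defined as 1.0 by convention")
        return 1.0
    return 2.0 * float((s & r).sum()) / denom


def sensitivity_specificity(
    seg: BinaryVolume, ref: BinaryVolume, domain: BinaryVolume
) -> tuple[float, float]:
    """Voxel confusion rates with negatives counted inside ``domain`` only."""
    check_same_geometry(seg, ref)
    check_same_geometry(domain, ref)
    if not ref.mask.any():
        raise ValueError("sensitivity undefined for an empty reference mask")
    if (ref.mask & ~domain.mask).any():
        raise ValueError("domain must contain the reference mask")
    s = seg.mask & domain.mask
    r = ref.mask
    tp = float((s & r).sum())
    fn = float((~s & r).sum())
    fp = float((s & ~r).sum())
    tn = float((~s & ~r & domain.mask).sum())
    return tp / (tp + fn), tn / (tn + fp)


def boundary_points_2d(mask2d: np.ndarray) -> np.ndarray:
    """Pixels of a 2D mask 8-adjacent to background (array edge counts as background)."""
    er = ndimage.binary_erosion(mask2d, structure=_STRUCT_8, border_value=0)
    return np.argwhere(mask2d & ~er)


def boundary_rmse(seg: BinaryVolume, ref: BinaryVolume, spacing=None) -> float:
    """RMS of per-point distances from the predicted boundary to the closest
    reference boundary point in the same slice, in mm.

    Slices where the prediction has a boundary but the reference does not are
    skipped (with a logged count) rather than matched across slices.
    """
    check_same_geometry(seg, ref)
    if not seg.mask.any() or not ref.mask.any():
        raise ValueError("boundary RMSE needs two nonempty masks")
    if spacing is None:
        spacing = seg.spacing
    scale = np.array(spacing[:2], dtype=float)

    sq_dists: list[np.ndarray] = []
    skipped = 0
    for z in range(seg.shape[2]):
        spts = boundary_points_2d(seg.mask[:, :, z])
        if spts.size == 0:
            continue
        rpts = boundary_points_2d(ref.mask[:, :, z])
        if rpts.size == 0:
            skipped += 1
            continue
        tree = cKDTree(rpts * scale)
        d, _ = tree.query(spts * scale, k=1)
        sq_dists.append(d**2)
    if skipped:
        logger.warning("boundary RMSE skipped %d slices without reference boundary", skipped)
    if not sq_dists:
        raise ValueError("no comparable boundary slices")
    return float(np.sqrt(np.concatenate(sq_dists).mean()))


def reliability(dices: list[float], d: float) -> float:
    """Fraction of cases with Dice strictly greater than d."""
    if len(dices) == 0:
        raise ValueError("empty Dice list")
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")
    arr = np.asarray(dices, dtype=float)
    return float((arr > d).mean())


def volume_correlation(vols_seg, vols_ref) -> float:
    """Pearson correlation between paired volumes."""
    a = np.asarray(vols_seg, dtype=float)
    b = np.asarray(vols_ref, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired volumes")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in volumes")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class EvalReport:
    """Per-case metric bundle."""

    case: int | str
    dice: float
    sensitivity: float
    specificity: float
    rmse_mm: float
    vol_seg_ml: float
    vol_ref_ml: float


def evaluate_case(
    seg: BinaryVolume,
    ref: BinaryVolume,
    domain: BinaryVolume,
    case: int | str = 0,
) -> EvalReport:
    """All per-case metrics against a reference mask."""
    sens, spec = sensitivity_specificity(seg, ref, domain)
    return EvalReport(
        case=case,
        dice=dice(seg, ref),
        sensitivity=sens,
        specificity=spec,
        rmse_mm=boundary_rmse(seg, ref),
        vol_seg_ml=seg.volume_ml(),
        vol_ref_ml=ref.volume_ml(),
    )


RELIABILITY_GRID = np.round(np.arange(0.50, 1.0001, 0.01), 2)
_METRICS = ["dice", "sensitivity", "specificity", "rmse_mm", "vol_seg_ml", "vol_ref_ml"]


@dataclass
class SuiteSummary:
    """Aggregated metrics over a suite of cases."""

    table: pd.DataFrame  # rows: metric; cols: mean, sd, min, max
    reliability_curve: pd.DataFrame  # columns: d, reliability
    volume_correlation: float
    per_case: pd.DataFrame
    sd_degenerate: bool = False


def summarize_suite(reports: list[EvalReport]) -> SuiteSummary:
    """Mean/SD(min/max) per metric, reliability curve and volume correlation."""
    if not reports:
        raise ValueError("no reports to summarize")
    per_case = pd.DataFrame([vars(r) for r in reports]).set_index("case")
    degenerate = len(reports) == 1
    table = pd.DataFrame(
        {
            "mean": per_case[_METRICS].mean(),
            "sd": per_case[_METRICS].std(ddof=1).fillna(0.0) if not degenerate else 0.0,
            "min": per_case[_METRICS].min(),
            "max": per_case[_METRICS].max(),
        }
    )
    dices = per_case["dice"].tolist()
    curve = pd.DataFrame(
        {"d": RELIABILITY_GRID, "reliability": [reliability(dices, d) for d in RELIABILITY_GRID]}
    )
    try:
        r = volume_correlation(per_case["vol_seg_ml"], per_case["vol_ref_ml"])
    except ValueError:
        r = float("nan")
    return SuiteSummary(table, curve, r, per_case, sd_degenerate=degenerate)
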