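"""Ventricular HU-range estimation.

The brain is split into a low/high intensity stratum by one-dimensional
2-means; the largest 3D connected component of the low stratum is the
candidate ventricle.  Its per-HU histogram is then tracked from the mode
outward: the first bin where the smoothed slope turns non-negative (or falls
below 2% of the peak count) marks the CSF / white-matter separator, which
becomes V_max; V_min mirrors the mode symmetrically and is clamped at 0.
When no separator is found inside the sanity band, the estimate falls back to
the 1-12 HU range that non-contrast CT ventricles occupy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator

from .volume import BinaryVolume, CTVolume, check_same_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityRange",
    "VentricleIntensityEstimator",
    "two_means_1d",
    "cluster_brain",
    "estimate_ventricle_range",
]

#: domain-knowledge fallback (HU band of ventricular CSF on head CT)
FALLBACK_RANGE = (1.0, 12.0)

#: sanity band for the estimated range (HU)
SANITY_BAND = (-5.0, 25.0)

#: a slope flatter than this fraction of the histogram peak counts as a valley
SLOPE_TOL_FRAC = 0.02

#: a valley is only accepted where the histogram has dropped to this fraction
#: of its peak: the CSF/white-matter gap is sparsely populated, whereas a dip
#: in front of an attached-lesion bump is not
VALLEY_DENSITY_FRAC = 0.20

#: upper bound on the separator, in left half-widths of the CSF peak above the
#: mode (the left flank is never contaminated by lesions or partial volume)
MAX_HALFWIDTHS_ABOVE_MODE = 2.2

#: hard ceiling on the CSF/white-matter separator: periventricular partial
#: volume and leukoaraiosis occupy roughly 18-25 HU, so a separator above
#: this level means the candidate histogram is contaminated (e.g. by an
#: attached lesion) and would pull halo tissue into the mask
SEPARATOR_CEILING_HU = 16.0

#: ceiling on the lower bound: ventricular CSF reaches ~1 HU, so a floor
#: above this value would cut into genuine CSF (it arises when an attached
#: lesion drags the apparent mode upward)
V_MIN_CEILING_HU = 4.0

#: a histogram local maximum needs this prominence (fraction of the global
#: peak) to count as a tissue mode of its own
PEAK_PROMINENCE_FRAC = 0.15

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _lloyd_1d(v: np.ndarray, c0: float, c1: float, tol: float, max_iter: int):
    for _ in range(max_iter):
        split = (c0 + c1) / 2.0
        low = v <= split
        if not low.any() or low.all():
            break
        n0, n1 = float(v[low].mean()), float(v[~low].mean())
        done = abs(n0 - c0) < tol and abs(n1 - c1) < tol
        c0, c1 = n0, n1
        if done:
            break
    split = (c0 + c1) / 2.0
    low = v <= split
    sse = float(((v[low] - c0) ** 2).sum() + ((v[~low] - c1) ** 2).sum())
    return split, (c0, c1), sse


def two_means_1d(values: np.ndarray, tol: float = 1e-3, max_iter: int = 200) -> tuple[float, tuple[float, float]]:
    """Deterministic 1D 2-means.

    Lloyd iterations are run from three deterministic center seedings (the
    10/90, 1/99 and 0/100 percentile pairs) and the lowest within-class SSE
    solution wins: a single percentile seeding can settle into a local
    optimum that splits the parenchyma instead of separating CSF from it,
    because the CSF class holds only a few percent of brain voxels.  Returns
    the class boundary (midpoint of the final centers) and the centers.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no values to cluster")
    if v.min() == v.max():
        raise ValueError("degenerate (constant) intensity distribution")
    seeds = []
    for plo, phi in ((10.0, 90.0), (1.0, 99.0), (0.0, 100.0)):
        c0, c1 = float(np.percentile(v, plo)), float(np.percentile(v, phi))
        if c0 < c1:
            seeds.append((c0, c1))
    if not seeds:
        seeds = [(float(v.min()), float(v.max()))]
    best = min((_lloyd_1d(v, c0, c1, tol, max_iter) for c0, c1 in seeds), key=lambda r: r[2])
    return best[0], best[1]


#: voxels above this are bone partial volume / calcification, not parenchyma,
#: and are excluded from the CSF-vs-parenchyma stratification
SOFT_TISSUE_MAX_HU = 80.0


def cluster_brain(vol: CTVolume, brain: BinaryVolume, soft_tissue_max: float = SOFT_TISSUE_MAX_HU) -> BinaryVolume:
    """Candidate ventricle: largest 3D component of the low 2-means stratum."""
    check_same_geometry(brain, vol)
    if not brain.mask.any():
        raise ValueError("empty brain mask")
    tissue = brain.mask & (vol.voxels <= soft_tissue_max)
    if not tissue.any():
        raise ValueError("no soft-tissue voxels inside the brain mask")
    split, _ = two_means_1d(vol.voxels[tissue])
    low = brain.mask & (vol.voxels <= split)
    labels, n = ndimage.label(low, structure=_STRUCT_26)
    if n == 0:
        raise ValueError("low-intensity stratum is empty")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return BinaryVolume(labels == sizes.argmax(), vol.spacing)


@dataclass
class IntensityRange:
    """Estimated ventricular HU bounds plus the histogram diagnostics."""

    v_min: float
    v_max: float
    critical_intensity: float
    histogram: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bin_centers: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fallback: bool = False

    def __post_init__(self) -> None:
        if not self.v_min < self.v_max:
            raise ValueError(f"require v_min < v_max, got ({self.v_min}, {self.v_max})")

    def percentile(self, q: float) -> float | None:
        """HU value at the q-th percentile of the candidate histogram, or
        ``None`` when no histogram was recorded."""
        counts = np.asarray(self.histogram, dtype=float)
        if counts.size == 0 or counts.sum() == 0:
            return None
        cum = np.cumsum(counts) / counts.sum()
        idx = int(np.searchsorted(cum, q / 100.0))
        return float(np.asarray(self.bin_centers)[min(idx, counts.size - 1)])


def _smooth3(counts: np.ndarray) -> np.ndarray:
    return ndimage.uniform_filter1d(counts.astype(float), size=3, mode="constant")


def estimate_ventricle_range(
    vol: CTVolume,
    candidate: BinaryVolume,
    slope_tol_frac: float = SLOPE_TOL_FRAC,
    sanity_band: tuple[float, float] = SANITY_BAND,
) -> IntensityRange:
    """Histogram-slope estimate of [V_min, V_max] from the candidate component."""
    check_same_geometry(candidate, vol)
    if not candidate.mask.any():
        raise ValueError("empty candidate component")
    vals = vol.voxels[candidate.mask]
    lo = int(np.floor(vals.min()))
    hi = int(np.ceil(vals.max()))
    edges = np.arange(lo, hi + 2) - 0.5
    counts, _ = np.histogram(vals, bins=edges)
    centers = np.arange(lo, hi + 1, dtype=float)
    smooth = _smooth3(counts.astype(float))

    # CSF is the darkest brain tissue, so its mode is the LEFTMOST prominent
    # peak; a large attached lesion can outweigh the CSF bulk and move the
    # global maximum without moving that leftmost peak
    global_peak = float(smooth.max())
    peak_idx, _ = signal.find_peaks(smooth, prominence=PEAK_PROMINENCE_FRAC * global_peak)
    mode_idx = int(peak_idx[0]) if peak_idx.size else int(np.argmax(smooth))
    peak = smooth[mode_idx]
    # robust mode position: centre of mass of the near-peak bins around the
    # chosen maximum (flat-topped CSF histograms otherwise give an arbitrary
    # argmax)
    top = smooth >= 0.8 * peak
    # restrict the averaging window to the contiguous run containing mode_idx
    left = mode_idx
    while left > 0 and top[left - 1]:
        left -= 1
    right = mode_idx
    while right < len(top) - 1 and top[right + 1]:
        right += 1
    sel = slice(left, right + 1)
    mode_hu = float(np.average(centers[sel], weights=smooth[sel]))
    # left half-width of the CSF peak; its left flank is never contaminated
    # by lesions, so it bounds how far the separator can plausibly sit
    below_half = np.flatnonzero((centers < mode_hu) & (smooth < 0.5 * peak))
    w_left = max(2.0, mode_hu - centers[below_half[-1]]) if below_half.size else 2.0

    critical = None
    for h in range(mode_idx + 1, len(smooth) - 1):
        if centers[h] <= mode_hu:
            continue
        slope = smooth[h + 1] - smooth[h]
        flatish = slope >= 0 or abs(slope) < slope_tol_frac * peak
        if flatish and smooth[h] <= VALLEY_DENSITY_FRAC * peak:
            critical = centers[h]
            break

    if critical is not None:
        critical = min(
            critical, mode_hu + MAX_HALFWIDTHS_ABOVE_MODE * w_left, SEPARATOR_CEILING_HU
        )
    if critical is None or not sanity_band[0] <= critical <= sanity_band[1]:
        logger.warning("no histogram valley found in the sanity band; using the domain fallback range")
        return IntensityRange(
            v_min=FALLBACK_RANGE[0],
            v_max=FALLBACK_RANGE[1],
            critical_intensity=FALLBACK_RANGE[1],
            histogram=counts,
            bin_centers=centers,
            fallback=True,
        )

    v_max = float(np.clip(critical, *sanity_band))
    v_min = float(np.clip(max(0.0, 2.0 * mode_hu - critical), *sanity_band))
    v_min = min(v_min, V_MIN_CEILING_HU)
    if not v_min < v_max:
        return IntensityRange(*FALLBACK_RANGE, FALLBACK_RANGE[1], counts, centers, fallback=True)
    return IntensityRange(v_min, v_max, float(critical), counts, centers)


class VentricleIntensityEstimator(BaseEstimator):
    """Estimate the ventricular HU range of one (aligned) brain volume.

    Attributes after ``fit``: ``candidate_mask_``, ``range_``, and the
    convenience scalars ``v_min_`` / ``v_max_`` / ``critical_intensity_``.
    """

    def __init__(self, slope_tol_frac: float = SLOPE_TOL_FRAC, sanity_band: tuple[float, float] = SANITY_BAND):
        self.slope_tol_frac = slope_tol_frac
        self.sanity_band = sanity_band

    def fit(self, vol: CTVolume, brain: BinaryVolume) -> "VentricleIntensityEstimator":
        self.candidate_mask_ = cluster_brain(vol, brain)
        self.range_ = estimate_ventricle_range(
            vol, self.candidate_mask_, self.slope_tol_frac, tuple(self.sanity_band)
        )
        self.v_min_ = self.range_.v_min
        self.v_max_ = self.range_.v_max
        self.critical_intensity_ = self.range_.critical_intensity
        return self
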