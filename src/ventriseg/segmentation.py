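"""Ventricle segmentation with three-scheme stroke exclusion.

The final mask is produced from an MSL-aligned volume by:

1. preliminary band thresholding ``f(t)`` at the estimated V_max, reduced to
   the largest 3D connected component (drops lesions not touching the
   ventricle);
2. an image-difference scheme for large edge-adjacent infarcts: a brain-edge
   annulus detector flags stroke tissue in the segmentation, an integer
   bisection finds the largest *clean* threshold T_critical, and the stroke
   mask PA = f(V_max) - g(f(T_critical)) is subtracted (g = per-slice closing
   plus dilation);
3. an adaptive template - the main body of the ventricle thresholded at a
   stricter level, closed and dilated - that removes small periventricular
   lesions and breaks their 3D bridges to the ventricle;

followed by refinement: largest component, per-slice closing, removal of
bright (calcified) voxels pulled in by the closing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from sklearn.base import BaseEstimator

from .alignment import BrainAligner, MidsagittalPlane, AlignmentTransform
from .intensity import IntensityRange, VentricleIntensityEstimator
from .volume import BinaryVolume, CTVolume, check_same_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "AnnulusConfig",
    "StrokeFinding",
    "SegmentationResult",
    "VentricleSegmenter",
    "threshold_segment",
    "largest_component_3d",
    "annulus_mask",
    "edge_check",
    "find_critical_threshold",
    "extract_stroke",
    "subtract_stroke",
    "build_template",
    "apply_template",
    "refine_mask",
    "segment_ventricle",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _disk_3d(radius: int) -> np.ndarray:
    """In-plane disk structuring element (1 slice thick): 5 mm slices make
    true 3D structuring elements badly anisotropic."""
    return disk(radius)[:, :, None].astype(bool)


@dataclass
class AnnulusConfig:
    """Brain-edge annulus detector settings."""

    width_fraction: float = 0.15
    area_threshold_px: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.width_fraction < 0.5:
            raise ValueError("width_fraction must lie in (0, 0.5)")
        if self.area_threshold_px < 1:
            raise ValueError("area_threshold_px must be >= 1")


@dataclass
class StrokeFinding:
    """Outcome of the brain-edge check / image-difference extraction."""

    detected: bool
    offending_regions: BinaryVolume
    pa_mask: BinaryVolume


@dataclass
class SegmentationResult:
    """Everything the pipeline produced, in both frames."""

    final: BinaryVolume  # original frame
    final_aligned: BinaryVolume
    preliminary: BinaryVolume  # aligned frame
    t_critical: float
    stroke: StrokeFinding
    template: BinaryVolume
    intensity_range: IntensityRange
    plane: MidsagittalPlane
    transform: AlignmentTransform
    brain_mask: BinaryVolume  # original frame
    brain_aligned: BinaryVolume
    aligned_volume: CTVolume
    edge_map: BinaryVolume | None = None  # light-curve detections, original frame
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations


def threshold_segment(vol: CTVolume, brain: BinaryVolume, t: float, v_min: float) -> BinaryVolume:
    """Band threshold f(t): brain voxels with v_min <= HU <= t."""
    check_same_geometry(brain, vol)
    if t < v_min:
        raise ValueError(f"threshold {t} below v_min {v_min}")
    mask = brain.mask & (vol.voxels >= v_min) & (vol.voxels <= t)
    return BinaryVolume(mask, vol.spacing)


def largest_component_3d(mask: BinaryVolume) -> BinaryVolume:
    """Largest 26-connected component; raster-order labelling breaks ties."""
    if not mask.mask.any():
        raise ValueError("cannot take the largest component of an empty mask")
    labels, _ = ndimage.label(mask.mask, structure=_STRUCT_26)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return BinaryVolume(labels == sizes.argmax(), mask.spacing)


def brain_lmin(brain: BinaryVolume) -> int:
    """Minimum side of the scan-wide brain bounding rectangle, in pixels."""
    cols = np.flatnonzero(brain.mask.any(axis=(1, 2)))
    rows = np.flatnonzero(brain.mask.any(axis=(0, 2)))
    return int(min(cols[-1] - cols[0] + 1, rows[-1] - rows[0] + 1))


def annulus_mask(brain: BinaryVolume, cfg: AnnulusConfig | None = None) -> BinaryVolume:
    """Per-slice band of brain voxels within 0.15*L_min of the brain edge."""
    if not brain.mask.any():
        raise ValueError("empty brain mask")
    cfg = cfg or AnnulusConfig()
    radius = max(1, int(round(cfg.width_fraction * brain_lmin(brain))))
    footprint = _disk_3d(radius)
    eroded = ndimage.binary_erosion(brain.mask, structure=footprint, border_value=0)
    return BinaryVolume(brain.mask & ~eroded, brain.spacing)


def edge_check(seg: BinaryVolume, annulus: BinaryVolume, cfg: AnnulusConfig | None = None) -> StrokeFinding:
    """Flag stroke if any slice's seg-annulus overlap area exceeds the threshold."""
    check_same_geometry(seg, annulus)
    cfg = cfg or AnnulusConfig()
    overlap = seg.mask & annulus.mask
    per_slice = overlap.sum(axis=(0, 1))
    hot_slices = per_slice > cfg.area_threshold_px  # strictly greater
    detected = bool(hot_slices.any())

    offending = np.zeros_like(seg.mask)
    if detected:
        labels, n = ndimage.label(seg.mask, structure=_STRUCT_26)
        for lab in range(1, n + 1):
            comp = labels == lab
            if (comp & annulus.mask)[:, :, hot_slices].any():
                offending |= comp
    empty = BinaryVolume(np.zeros_like(seg.mask), seg.spacing)
    return StrokeFinding(detected, BinaryVolume(offending, seg.spacing), empty)


def _clean_at(vol, brain, annulus, t, v_min, cfg) -> bool:
    seg = threshold_segment(vol, brain, t, v_min)
    if not seg.mask.any():
        return True
    seg = largest_component_3d(seg)
    return not edge_check(seg, annulus, cfg).detected


def find_critical_threshold(
    vol: CTVolume,
    brain: BinaryVolume,
    rng: IntensityRange,
    cfg: AnnulusConfig | None = None,
    annulus: BinaryVolume | None = None,
) -> float:
    """Largest integer threshold in [V_min, V_max] whose largest component
    passes the edge check.

    The detection predicate is monotone in t (raising the threshold only adds
    voxels), so an integer bisection finds the boundary.
    """
    cfg = cfg or AnnulusConfig()
    if annulus is None:
        annulus = annulus_mask(brain, cfg)
    lo = int(np.ceil(rng.v_min))
    hi = int(np.floor(rng.v_max))
    if hi < lo:
        return rng.v_min
    if _clean_at(vol, brain, annulus, hi, rng.v_min, cfg):
        return float(hi)
    if not _clean_at(vol, brain, annulus, lo, rng.v_min, cfg):
        logger.warning("edge check fails even at V_min=%s; returning V_min", rng.v_min)
        return float(lo)
    # invariant: clean at lo, not clean at hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _clean_at(vol, brain, annulus, mid, rng.v_min, cfg):
            lo = mid
        else:
            hi = mid
    return float(lo)


def _close_then_dilate(mask: np.ndarray, close_r: int, dilate_r: int) -> np.ndarray:
    out = mask
    if close_r > 0:
        out = ndimage.binary_closing(out, structure=_disk_3d(close_r))
    if dilate_r > 0:
        out = ndimage.binary_dilation(out, structure=_disk_3d(dilate_r))
    return out


def extract_stroke(
    vol: CTVolume,
    brain: BinaryVolume,
    rng: IntensityRange,
    t_critical: float,
    cfg: AnnulusConfig | None = None,
    annulus: BinaryVolume | None = None,
    close_radius: int = 2,
    dilate_radius: int = 1,
) -> StrokeFinding:
    """Image-difference stroke mask PA = f(V_max) - g(f(T_critical)),
    restricted to components that touch the brain-edge annulus."""
    cfg = cfg or AnnulusConfig()
    if annulus is None:
        annulus = annulus_mask(brain, cfg)
    full = threshold_segment(vol, brain, rng.v_max, rng.v_min).mask
    # the benchmark ventricular mask is the segmentation *result* at
    # T_critical - thresholding followed by the largest-component step - so
    # that fragmented sub-threshold lesion speckle cannot re-enter via the
    # morphological closing
    bench = threshold_segment(vol, brain, t_critical, rng.v_min)
    if bench.mask.any():
        bench = largest_component_3d(bench)
    pa = full & ~_close_then_dilate(bench.mask, close_radius, dilate_radius)

    kept = np.zeros_like(pa)
    if pa.any():
        labels, n = ndimage.label(pa, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            # noise-sized fragments (the morphology margin of the difference)
            # are not stroke tissue
            if sizes[lab] < cfg.area_threshold_px:
                continue
            comp = labels == lab
            if (comp & annulus.mask).any():
                kept |= comp
    detected = bool(kept.any())
    return StrokeFinding(detected, BinaryVolume(kept.copy(), vol.spacing), BinaryVolume(kept, vol.spacing))


def subtract_stroke(
    preliminary: BinaryVolume,
    pa: StrokeFinding,
    close_radius: int = 2,
    dilate_radius: int = 1,
) -> BinaryVolume:
    """Ventricle after stroke removal: preliminary minus g(PA)."""
    check_same_geometry(pa.pa_mask, preliminary)
    if not pa.pa_mask.mask.any():
        return preliminary.copy()
    grown = _close_then_dilate(pa.pa_mask.mask, close_radius, dilate_radius)
    return BinaryVolume(preliminary.mask & ~grown, preliminary.spacing)


def build_template(
    vol: CTVolume,
    brain: BinaryVolume,
    rng: IntensityRange,
    min_voxels: int = 100,
    close_radius: int = 2,
    dilate_radius: int = 3,
) -> BinaryVolume:
    """Adaptive main-body ventricle template.

    Thresholds at V_min first; when that selects almost nothing (V_min sits at
    the very bottom of the band) it retries at the band midpoint.  The largest
    3D component is closed and dilated per slice so the template covers the
    ventricle body while still excluding edge-adjacent lesions.
    """
    core = template_core(vol, brain, rng, min_voxels, close_radius)
    if not core.mask.any():
        logger.warning("template empty even at the band midpoint; template stage disabled")
        return core
    grown = ndimage.binary_dilation(core.mask, structure=_disk_3d(dilate_radius))
    return BinaryVolume(grown, vol.spacing)


#: a template level is adequate when it selects at least this fraction of the
#: full-band segmentation (the template must cover the ventricle main body)
TEMPLATE_MIN_FRACTION = 0.25


def template_core(
    vol: CTVolume,
    brain: BinaryVolume,
    rng: IntensityRange,
    min_voxels: int = 100,
    close_radius: int = 2,
) -> BinaryVolume:
    """Main ventricle body at a strict template threshold (closed, before the
    covering dilation).

    Levels are tried from strict to permissive: V_min itself, the 25th
    percentile of the candidate-component histogram (deep inside the CSF
    bulk, hence robust to attached-lesion contamination), and finally the
    band midpoint.  A level is accepted once it selects both an absolute
    minimum of voxels and a meaningful fraction of the full-band mask; empty
    otherwise.
    """
    full_count = threshold_segment(vol, brain, rng.v_max, rng.v_min).count()
    levels = [rng.v_min]
    p25 = rng.percentile(25.0)
    if p25 is not None:
        levels.append(max(p25, rng.v_min))
    levels.append((rng.v_min + rng.v_max) / 2.0)
    for level in levels:
        core = threshold_segment(vol, brain, level, rng.v_min)
        if core.count() >= max(min_voxels, TEMPLATE_MIN_FRACTION * full_count):
            core = largest_component_3d(core)
            closed = ndimage.binary_closing(core.mask, structure=_disk_3d(close_radius))
            return BinaryVolume(closed, vol.spacing)
    return BinaryVolume(np.zeros(vol.shape, dtype=bool), vol.spacing)


def apply_template(seg: BinaryVolume, template: BinaryVolume, max_spill_px: int = 20) -> BinaryVolume:
    """Keep the objects within the template.

    Components with zero template overlap are dropped.  For retained
    components, voxels outside the template are removed when their per-slice
    2D blob reaches ``max_spill_px`` (a lesion poking out), and kept when
    smaller (true ventricle edge slightly exceeding the template).  Removing
    the large blobs is what breaks lesion-ventricle bridges in 3D.
    """
    check_same_geometry(template, seg)
    if not template.mask.any():
        return seg.copy()

    labels, n = ndimage.label(seg.mask, structure=_STRUCT_26)
    overlap_labels = np.unique(labels[template.mask & seg.mask])
    keep3d = np.isin(labels, overlap_labels[overlap_labels > 0])

    out = keep3d.copy()
    spill = keep3d & ~template.mask
    struct2d = np.ones((3, 3), dtype=bool)
    for z in range(seg.shape[2]):
        sl = spill[:, :, z]
        if not sl.any():
            continue
        lab2d, m = ndimage.label(sl, structure=struct2d)
        sizes = np.bincount(lab2d.ravel())
        big = sizes >= max_spill_px
        big[0] = False
        out[:, :, z] &= ~big[lab2d]
    return BinaryVolume(out, seg.spacing)


def refine_mask(
    vol: CTVolume,
    seg: BinaryVolume,
    v_max: float,
    close_radius: int = 2,
    calcification_margin: float = 30.0,
) -> BinaryVolume:
    """Final cleanup: largest component, per-slice closing, calcification
    removal (HU above v_max + margin), largest component again."""
    check_same_geometry(seg, vol)
    if not seg.mask.any():
        raise ValueError("segmentation failure: empty mask before refinement")
    out = largest_component_3d(seg).mask
    out = ndimage.binary_closing(out, structure=_disk_3d(close_radius))
    out = out & ~(vol.voxels > v_max + calcification_margin)
    if not out.any():
        raise ValueError("segmentation failure: refinement removed every voxel")
    return largest_component_3d(BinaryVolume(out, seg.spacing))


# ---------------------------------------------------------------------------
# orchestration


class VentricleSegmenter(BaseEstimator):
    """End-to-end ventricle segmentation of one head-CT volume.

    ``fit`` runs alignment, intensity estimation and the three stroke-exclusion
    schemes, recording every intermediate; ``predict`` returns the final mask
    in the original (unaligned) frame.
    """

    def __init__(
        self,
        annulus_width_fraction: float = 0.15,
        annulus_area_threshold: int = 20,
        stroke_close_radius: int = 2,
        stroke_dilate_radius: int = 1,
        template_close_radius: int = 2,
        template_dilate_radius: int = 3,
        template_min_voxels: int = 100,
        refine_close_radius: int = 2,
        calcification_margin: float = 30.0,
        template_max_spill_px: int = 20,
        min_component_voxels: int = 30,
        edge_k: float = 2.5,
        slope_tol_frac: float = 0.02,
    ):
        self.annulus_width_fraction = annulus_width_fraction
        self.annulus_area_threshold = annulus_area_threshold
        self.stroke_close_radius = stroke_close_radius
        self.stroke_dilate_radius = stroke_dilate_radius
        self.template_close_radius = template_close_radius
        self.template_dilate_radius = template_dilate_radius
        self.template_min_voxels = template_min_voxels
        self.refine_close_radius = refine_close_radius
        self.calcification_margin = calcification_margin
        self.template_max_spill_px = template_max_spill_px
        self.min_component_voxels = min_component_voxels
        self.edge_k = edge_k
        self.slope_tol_frac = slope_tol_frac

    def fit(self, vol: CTVolume, y=None) -> "VentricleSegmenter":
        log: list[str] = []
        cfg = AnnulusConfig(self.annulus_width_fraction, self.annulus_area_threshold)

        aligner = BrainAligner(self.min_component_voxels, self.edge_k).fit(vol)
        aligned = aligner.transform(vol)
        brain_al = aligner.transform_mask(aligner.brain_mask_)
        log.append(
            f"alignment: tilt={aligner.tilt_deg_:.2f} deg, "
            f"fallback={aligner.plane_.fallback}, points={aligner.plane_.n_points}"
        )

        est = VentricleIntensityEstimator(self.slope_tol_frac).fit(aligned, brain_al)
        rng = est.range_
        log.append(
            f"intensity: v_min={rng.v_min:.1f}, v_max={rng.v_max:.1f}, "
            f"critical={rng.critical_intensity:.1f}, fallback={rng.fallback}"
        )

        preliminary = largest_component_3d(threshold_segment(aligned, brain_al, rng.v_max, rng.v_min))
        annulus = annulus_mask(brain_al, cfg)
        finding = edge_check(preliminary, annulus, cfg)
        log.append(f"edge check: detected={finding.detected}")

        if finding.detected:
            t_crit = find_critical_threshold(aligned, brain_al, rng, cfg, annulus)
            finding = extract_stroke(
                aligned, brain_al, rng, t_crit, cfg, annulus,
                self.stroke_close_radius, self.stroke_dilate_radius,
            )
            # the difference subtracts from the full band mask, not from the
            # preliminary largest component: when a lesion complex
            # outweighs the ventricle, the largest component IS the lesion,
            # and the ventricle must be recoverable after subtraction
            full_band = threshold_segment(aligned, brain_al, rng.v_max, rng.v_min)
            seg = subtract_stroke(full_band, finding, self.stroke_close_radius, self.stroke_dilate_radius)
            log.append(f"image difference: t_critical={t_crit:.0f}, PA voxels={finding.pa_mask.count()}")
        else:
            t_crit = rng.v_max
            seg = preliminary.copy()
            log.append("image difference skipped (no edge finding)")

        template = build_template(
            aligned, brain_al, rng,
            self.template_min_voxels, self.template_close_radius, self.template_dilate_radius,
        )
        seg = apply_template(seg, template, self.template_max_spill_px)
        log.append(f"template: voxels={template.count()}, seg after template={seg.count()}")

        final_aligned = refine_mask(
            aligned, seg, rng.v_max, self.refine_close_radius, self.calcification_margin
        )
        final = aligner.transform_.inverse_mask(final_aligned)
        log.append(f"final voxels={final.count()}")

        self.aligner_ = aligner
        self.result_ = SegmentationResult(
            final=final,
            final_aligned=final_aligned,
            preliminary=preliminary,
            t_critical=float(t_crit),
            stroke=finding,
            template=template,
            intensity_range=rng,
            plane=aligner.plane_,
            transform=aligner.transform_,
            brain_mask=aligner.brain_mask_,
            brain_aligned=brain_al,
            aligned_volume=aligned,
            edge_map=aligner.edge_map_,
            log=log,
        )
        return self

    def predict(self, vol: CTVolume | None = None) -> BinaryVolume:
        if vol is not None:
            self.fit(vol)
        return self.result_.final

    def fit_predict(self, vol: CTVolume) -> BinaryVolume:
        return self.fit(vol).predict()


def segment_ventricle(vol: CTVolume, **params) -> SegmentationResult:
    """Functional entry point; see :class:`VentricleSegmenter`."""
    return VentricleSegmenter(**params).fit(vol).result_
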