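"""Segmentation operators and the end-to-end stroke-exclusion pipeline."""
import numpy as np
import pytest
from scipy import ndimage

from ventriseg.alignment import strip_skull
from ventriseg.intensity import IntensityRange
from ventriseg.phantom import LesionSpec, generate_phantom
from ventriseg.segmentation import (
    AnnulusConfig,
    VentricleSegmenter,
    annulus_mask,
    apply_template,
    build_template,
    edge_check,
    extract_stroke,
    find_critical_threshold,
    largest_component_3d,
    refine_mask,
    segment_ventricle,
    subtract_stroke,
    threshold_segment,
)
from ventriseg.evaluation import dice
from ventriseg.volume import BinaryVolume, CTVolume

from conftest import small_spec


def exhaustive_critical_threshold(vol, brain, rng, cfg, annulus):
    """Oracle: scan every integer threshold from the top down."""
    lo = int(np.ceil(rng.v_min))
    hi = int(np.floor(rng.v_max))
    for t in range(hi, lo - 1, -1):
        seg = threshold_segment(vol, brain, t, rng.v_min)
        if not seg.mask.any():
            return float(t)
        seg = largest_component_3d(seg)
        if not edge_check(seg, annulus, cfg).detected:
            return float(t)
    return float(lo)


def _box_volume(value=30.0, shape=(40, 40, 4)):
    return CTVolume(np.full(shape, value, dtype=np.float32), (1, 1, 1))


def _full_brain(shape=(40, 40, 4)):
    return BinaryVolume(np.ones(shape, dtype=bool), (1, 1, 1))


# ----------------------------------------------------------------- threshold

def test_threshold_band_and_monotonicity():
    rng = np.random.default_rng(0)
    voxels = rng.integers(-5, 30, size=(20, 20, 4)).astype(np.float32)
    vol = CTVolume(voxels, (1, 1, 1))
    brain = _full_brain((20, 20, 4))
    at_vmin = threshold_segment(vol, brain, 3.0, 3.0)
    assert np.array_equal(at_vmin.mask, voxels == 3.0)
    for t1, t2 in [(3, 7), (7, 12), (12, 20)]:
        m1 = threshold_segment(vol, brain, t1, 0.0).mask
        m2 = threshold_segment(vol, brain, t2, 0.0).mask
        assert not (m1 & ~m2).any()  # f(t1) subset of f(t2)


def test_noise_free_threshold_recovers_truth_exactly(clean_phantom):
    """On a noise-free, blur-free phantom the largest component of f(12)
    equals the ground-truth ventricle voxel for voxel."""
    vol, truth = clean_phantom
    brain = strip_skull(vol)
    seg = largest_component_3d(threshold_segment(vol, brain, 12.0, 1.0))
    assert np.array_equal(seg.mask, truth.ventricle_mask.mask)


# ---------------------------------------------------------------- largest CC

def test_largest_component_picks_bigger_blob_and_is_deterministic():
    mask = np.zeros((30, 30, 3), dtype=bool)
    mask[1:6, 1:5, 1] = True  # 20 voxels
    mask[10:20, 10:20, 1] = True  # 100 voxels
    out = largest_component_3d(BinaryVolume(mask, (1, 1, 1)))
    assert out.count() == 100 and out.mask[15, 15, 1]
    # equal-size blobs: raster-first wins, stable across runs
    tie = np.zeros((30, 30, 3), dtype=bool)
    tie[2:4, 2:4, 1] = True
    tie[20:22, 20:22, 1] = True
    o1 = largest_component_3d(BinaryVolume(tie, (1, 1, 1)))
    o2 = largest_component_3d(BinaryVolume(tie, (1, 1, 1)))
    assert np.array_equal(o1.mask, o2.mask)
    assert o1.mask[2, 2, 1] and not o1.mask[20, 20, 1]


def test_largest_component_empty_raises():
    with pytest.raises(ValueError):
        largest_component_3d(BinaryVolume(np.zeros((5, 5, 3), dtype=bool), (1, 1, 1)))


# -------------------------------------------------------------------- annulus

def test_annulus_of_filled_rectangle_is_exact_frame():
    mask = np.zeros((140, 240, 3), dtype=bool)
    mask[20:120, 20:220, 1] = True  # 100 x 200 rectangle
    brain = BinaryVolume(mask, (1, 1, 1))
    ann = annulus_mask(brain)  # L_min = 100 -> width 15
    expected = mask.copy()
    expected[35:105, 35:205, 1] = False
    assert np.array_equal(ann.mask, expected)
    assert ann.count() == 100 * 200 - 70 * 170


def test_annulus_inside_brain_and_disjoint_from_interior(noisy_phantom):
    vol, truth = noisy_phantom
    brain = strip_skull(vol)
    ann = annulus_mask(brain)
    assert not (ann.mask & ~brain.mask).any()
    # the centred ventricle never reaches the brain-edge band
    assert not (ann.mask & truth.ventricle_mask.mask).any()


# ----------------------------------------------------------------- edge check

def test_edge_check_area_threshold_is_strict():
    shape = (50, 50, 3)
    ann = np.zeros(shape, dtype=bool)
    ann[0:10, :, :] = True
    for area, expected in [(20, False), (25, True)]:
        seg = np.zeros(shape, dtype=bool)
        seg[0:5, 0 : area // 5, 1] = True
        finding = edge_check(BinaryVolume(seg, (1, 1, 1)), BinaryVolume(ann, (1, 1, 1)))
        assert finding.detected is expected
        assert finding.detected == bool(finding.offending_regions.count())
    outside = np.zeros(shape, dtype=bool)
    outside[30:45, 30:45, 1] = True
    assert not edge_check(BinaryVolume(outside, (1, 1, 1)), BinaryVolume(ann, (1, 1, 1))).detected


# ---------------------------------------------------- critical threshold

@pytest.fixture(scope="module")
def stroke_phantom():
    """Phantom with a large edge lesion bridging to the ventricle."""
    spec = small_spec(
        tilt_deg=3.0,
        seed=31,
        stroke_spec=[
            LesionSpec(radius_mm=22.0, hu_range=(7.0, 13.0), placement="fixed", center_mm=(28.0, 0.0))
        ],
    )
    return generate_phantom(spec)


def test_critical_threshold_clean_case_returns_vmax(noisy_phantom):
    vol, _ = noisy_phantom
    brain = strip_skull(vol)
    rng = IntensityRange(0.0, 13.0, 13.0)
    assert find_critical_threshold(vol, brain, rng) == 13.0


@pytest.mark.parametrize("seed", [31, 32, 33])
def test_critical_threshold_equals_exhaustive_scan(seed):
    spec = small_spec(
        tilt_deg=2.0,
        seed=seed,
        stroke_spec=[LesionSpec(radius_mm=20.0, hu_range=(7.5, 13.5), placement="edge")],
    )
    vol, _ = generate_phantom(spec)
    brain = strip_skull(vol)
    cfg = AnnulusConfig()
    ann = annulus_mask(brain, cfg)
    rng = IntensityRange(0.0, 14.0, 14.0)
    bisected = find_critical_threshold(vol, brain, rng, cfg, ann)
    oracle = exhaustive_critical_threshold(vol, brain, rng, cfg, ann)
    assert bisected == oracle


# ----------------------------------------------------- stroke extraction

def test_extract_stroke_identities(noisy_phantom):
    vol, _ = noisy_phantom
    brain = strip_skull(vol)
    rng = IntensityRange(0.0, 13.0, 13.0)
    finding = extract_stroke(vol, brain, rng, 13.0)
    # t_critical == v_max: PA is morphology margin only, treated as empty
    assert finding.pa_mask.count() == 0
    pre = largest_component_3d(threshold_segment(vol, brain, 13.0, 0.0))
    assert np.array_equal(subtract_stroke(pre, finding).mask, pre.mask)


def test_subtracted_result_is_disjoint_from_pa(stroke_phantom):
    vol, truth = stroke_phantom
    brain = strip_skull(vol)
    rng = IntensityRange(0.0, 14.0, 14.0)
    t_crit = find_critical_threshold(vol, brain, rng)
    finding = extract_stroke(vol, brain, rng, t_crit)
    pre = largest_component_3d(threshold_segment(vol, brain, 14.0, 0.0))
    out = subtract_stroke(pre, finding)
    assert not (out.mask & finding.pa_mask.mask).any()
    # PA avoids the benchmark's grown ventricle mask by construction
    bench = largest_component_3d(threshold_segment(vol, brain, t_crit, 0.0))
    assert not (finding.pa_mask.mask & bench.mask).any()


def test_extract_stroke_covers_most_of_a_bridged_lesion(stroke_phantom):
    vol, truth = stroke_phantom
    brain = strip_skull(vol)
    rng = IntensityRange(0.0, 14.0, 14.0)
    ann = annulus_mask(brain)
    pre = largest_component_3d(threshold_segment(vol, brain, 14.0, 0.0))
    assert edge_check(pre, ann).detected  # lesion bridged into the ventricle CC
    t_crit = find_critical_threshold(vol, brain, rng)
    assert t_crit < 7.5  # below the lesion's HU band
    finding = extract_stroke(vol, brain, rng, t_crit)
    out = subtract_stroke(pre, finding)
    residue = (out.mask & truth.stroke_mask.mask).sum() / truth.stroke_mask.count()
    assert residue <= 0.05


# -------------------------------------------------------------------- template

def test_template_covers_ventricle_and_excludes_edge_lesion(stroke_phantom):
    vol, truth = stroke_phantom
    brain = strip_skull(vol)
    rng = IntensityRange(0.0, 13.0, 13.0)
    template = build_template(vol, brain, rng)
    covered = (template.mask & truth.ventricle_mask.mask).sum() / truth.ventricle_mask.count()
    assert covered >= 0.95
    lesion_in = (template.mask & truth.stroke_mask.mask).sum() / truth.stroke_mask.count()
    assert lesion_in <= 0.25  # only the contact margin may enter


def test_apply_template_keeps_subsets_and_drops_disjoint_blobs():
    shape = (40, 40, 3)
    template = np.zeros(shape, dtype=bool)
    template[5:25, 5:25, :] = True
    seg = np.zeros(shape, dtype=bool)
    seg[8:20, 8:20, 1] = True
    tpl = BinaryVolume(template, (1, 1, 1))
    out = apply_template(BinaryVolume(seg, (1, 1, 1)), tpl)
    assert np.array_equal(out.mask, seg)
    seg2 = seg.copy()
    seg2[30:36, 30:36, 1] = True  # disjoint from the template
    out2 = apply_template(BinaryVolume(seg2, (1, 1, 1)), tpl)
    assert np.array_equal(out2.mask, seg)


def test_apply_template_spill_rule_removes_large_outside_blobs_only():
    shape = (60, 60, 3)
    template = np.zeros(shape, dtype=bool)
    template[10:40, 10:40, :] = True
    seg = np.zeros(shape, dtype=bool)
    seg[10:38, 12:38, 1] = True
    seg[38:48, 20:30, 1] = True  # attached blob whose outside part is 80 px
    seg[8:10, 12:14, 1] = True  # attached 4 px spill: tolerated
    out = apply_template(
        BinaryVolume(seg, (1, 1, 1)), BinaryVolume(template, (1, 1, 1)), max_spill_px=20
    )
    assert not out.mask[44, 25, 1]
    assert out.mask[8, 13, 1]
    assert out.mask[20, 20, 1]


def test_apply_template_empty_template_passes_through():
    seg = np.zeros((10, 10, 3), dtype=bool)
    seg[2:5, 2:5, 1] = True
    out = apply_template(
        BinaryVolume(seg, (1, 1, 1)), BinaryVolume(np.zeros_like(seg), (1, 1, 1))
    )
    assert np.array_equal(out.mask, seg)


# ------------------------------------------------------------------ refinement

def test_refine_fills_notch_and_removes_bright_voxels():
    vol = _box_volume(10.0, (40, 40, 3))
    seg = np.zeros((40, 40, 3), dtype=bool)
    seg[10:30, 10:30, 1] = True
    # 1 px wide, 2 px deep notch: the disk element cannot reach its inner
    # pixel from outside, so closing restores it
    seg[20, 10:12, 1] = False
    vol.voxels[15, 15, 1] = 80.0  # calcification inside the mask
    out = refine_mask(vol, BinaryVolume(seg, (1, 1, 1)), v_max=13.0)
    assert out.mask[20, 11, 1]  # inner notch pixel closed
    assert not out.mask[15, 15, 1]  # bright voxel removed


def test_refine_leaves_smooth_component_unchanged():
    vol = _box_volume(10.0, (40, 40, 3))
    seg = np.zeros((40, 40, 3), dtype=bool)
    seg[10:30, 10:30, :] = True
    out = refine_mask(vol, BinaryVolume(seg, (1, 1, 1)), v_max=13.0)
    assert np.array_equal(out.mask, seg)


def test_refine_empty_mask_is_a_segmentation_failure():
    vol = _box_volume()
    with pytest.raises(ValueError):
        refine_mask(vol, BinaryVolume(np.zeros(vol.shape, dtype=bool), (1, 1, 1)), v_max=13.0)


# ------------------------------------------------------------------ pipeline

def test_pipeline_without_stroke_skips_difference_branch(noisy_phantom):
    vol, truth = noisy_phantom
    result = segment_ventricle(vol)
    assert not result.stroke.detected
    assert result.t_critical == result.intensity_range.v_max
    assert dice(result.final, truth.ventricle_mask) >= 0.90
    # final mask is one 26-connected component inside the brain
    _, n = ndimage.label(result.final_aligned.mask, structure=np.ones((3, 3, 3)))
    assert n == 1


def test_pipeline_excludes_bridged_edge_stroke(stroke_phantom):
    vol, truth = stroke_phantom
    result = segment_ventricle(vol)
    assert result.stroke.detected
    residue = (result.final.mask & truth.stroke_mask.mask).sum() / truth.stroke_mask.count()
    assert residue <= 0.05
    # stroke exclusion trades a little ventricle near the contact zone; the
    # mask must still be a good ventricle segmentation
    assert dice(result.final, truth.ventricle_mask) >= 0.85


def test_pipeline_is_deterministic(noisy_phantom):
    vol, _ = noisy_phantom
    m1 = VentricleSegmenter().fit_predict(vol)
    m2 = VentricleSegmenter().fit_predict(vol)
    assert np.array_equal(m1.mask, m2.mask)


def test_estimators_follow_sklearn_conventions():
    from sklearn.base import clone

    seg = VentricleSegmenter(annulus_area_threshold=25)
    params = seg.get_params()
    assert params["annulus_area_threshold"] == 25
    cloned = clone(seg)
    assert cloned.get_params() == params
    seg.set_params(edge_k=3.0)
    assert seg.get_params()["edge_k"] == 3.0
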