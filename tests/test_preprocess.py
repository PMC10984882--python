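"""Enhancement chain: per-stage contracts, brute-force oracles, invariants."""

import numpy as np
import pytest
from skimage import morphology as skmorph

from eauscan.phantom import generate_phantom
from eauscan.preprocess import (
    PipelineStageError,
    PreprocessParams,
    UltrasoundPreprocessor,
    binarize,
    cir,
    detect_color_marks,
    find_solid_circle,
    inpaint,
    largest_bbox,
    local_contrast,
    preprocess_pipeline,
    remove_small_spots,
    select_se_radius,
    tophat_bothat_enhance,
    to_grayscale,
)


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and loop-based)

def contrast_oracle(gray, window=3):
    h, w = gray.shape
    r = window // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di == 0 and dj == 0:
                        continue
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w:
                        vals.append(gray[y, x])
            a = sum(vals) / len(vals)
            p = gray[i, j]
            out[i, j] = abs(p - a) / (p + a) if (p + a) != 0 else 0.0
    return out


def cir_oracle(orig, enh, window=3):
    c = contrast_oracle(orig, window)
    ce = contrast_oracle(enh, window)
    num = den = 0.0
    for i in range(orig.shape[0]):
        for j in range(orig.shape[1]):
            num += (c[i, j] - ce[i, j]) ** 2
            den += c[i, j] ** 2
    return num / den


def components_oracle(binary):
    """Flood-fill 8-connected component enumeration."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], []
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# colored-mark detection

def test_color_marks_gray_image_empty():
    gray = np.repeat(np.random.default_rng(0).integers(0, 255, (20, 20))[:, :, None], 3, axis=2)
    assert not detect_color_marks(gray, 20).any()


def test_color_marks_single_green_pixel():
    img = np.full((10, 10, 3), 100, dtype=np.uint8)
    img[4, 6] = (0, 255, 0)
    mask = detect_color_marks(img, 20)
    assert mask[4, 6] and mask.sum() == 1


def test_color_marks_cover_phantom_annotations(lesion_phantom_spec):
    rec = generate_phantom(lesion_phantom_spec)
    mask = detect_color_marks(rec.pixels, 20)
    truth = rec.masks["marks"]
    assert truth.sum() > 0
    assert (mask & truth).sum() / truth.sum() >= 0.95


def test_color_marks_rejects_grayscale_array():
    with pytest.raises(TypeError):
        detect_color_marks(np.zeros((5, 5)), 20)


# ---------------------------------------------------------------------------
# inpainting

def test_inpaint_empty_mask_identity():
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 255, (12, 12))
    out = inpaint(img, np.zeros((12, 12), bool))
    assert np.array_equal(out, img)


def test_inpaint_constant_fixed_point():
    img = np.full((15, 15), 50.0)
    mask = np.zeros((15, 15), bool)
    mask[5:9, 5:9] = True
    out = inpaint(img, mask)
    assert np.allclose(out, 50.0, atol=1e-6)


def test_inpaint_ramp_gap_linear():
    """Harmonic fill of a 1-D gap in a linear ramp is the linear interpolant."""
    img = np.tile(np.arange(20, dtype=float) * 10, (5, 1))
    mask = np.zeros_like(img, dtype=bool)
    mask[:, 8:11] = True
    out = inpaint(img, mask, tol=0.01)
    assert np.abs(out[:, 8:11] - img[:, 8:11]).max() <= 1.0
    assert np.array_equal(out[~mask], img[~mask])


def test_inpaint_full_mask_errors():
    with pytest.raises(ValueError, match="entire image"):
        inpaint(np.zeros((4, 4)), np.ones((4, 4), bool))


# ---------------------------------------------------------------------------
# binarize / bounding box / spot removal

def test_binarize_strict_boundary():
    img = np.array([[8.0, 9.0], [0.0, 255.0]])
    assert binarize(img, 8).tolist() == [[False, True], [False, True]]
    assert not binarize(np.zeros((3, 3)), 8).any()


def test_binarize_covers_phantom_field(normal_spec):
    rec = generate_phantom(normal_spec)
    binary = binarize(to_grayscale(rec.pixels), 8)
    field = rec.masks["field"]
    assert binary[field].mean() > 0.9


def test_largest_bbox_cases():
    single = np.zeros((10, 10), bool)
    single[5, 7] = True
    assert largest_bbox(single) == (5, 7, 6, 8)
    assert largest_bbox(np.ones((6, 9), bool)) == (0, 0, 6, 9)
    with pytest.raises(ValueError, match="no foreground"):
        largest_bbox(np.zeros((4, 4), bool))


def test_largest_bbox_two_blobs_picks_larger():
    img = np.zeros((30, 30), bool)
    img[2:12, 2:12] = True  # area 100
    img[20:26, 20:25] = True  # area 30
    assert largest_bbox(img) == (2, 2, 12, 12)


def test_largest_bbox_matches_flood_fill_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        img = rng.random((14, 14)) < 0.35
        if not img.any():
            continue
        comps = components_oracle(img)
        best = max(comps, key=lambda c: (len(c), -min(c)[0], -min(p[1] for p in c)))
        rows = [p[0] for p in best]
        cols = [p[1] for p in best]
        expected = (min(rows), min(cols), max(rows) + 1, max(cols) + 1)
        assert largest_bbox(img) == expected


def test_remove_small_spots_boundary_rule():
    img = np.zeros((20, 40), bool)
    img[2:9, 2:9] = True  # area 49 = min-1 -> removed
    img[2:9, 20:27] = True
    img[8, 27] = True  # grow to exactly 50 (8-connected) -> kept
    out = remove_small_spots(img, min_spot_area=50)
    assert not out[2:9, 2:9].any()
    assert out[2:9, 20:27].all()


def test_remove_small_spots_matches_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        img = rng.random((16, 16)) < 0.4
        out = remove_small_spots(img, min_spot_area=5)
        expected = sum(1 for c in components_oracle(img) if len(c) >= 5)
        assert len(components_oracle(out)) == expected


# ---------------------------------------------------------------------------
# solid circle

def test_find_solid_circle_recovers_synthetic_disc():
    yy, xx = np.mgrid[0:120, 0:120]
    disc = np.hypot(xx - 60, yy - 60) <= 40
    circle, mask = find_solid_circle(disc)
    assert circle is not None
    cx, cy, r = circle
    assert abs(r - 40) <= 2 and abs(cx - 60) <= 2 and abs(cy - 60) <= 2
    assert mask.any()


def test_find_solid_circle_rejects_thin_ring():
    yy, xx = np.mgrid[0:120, 0:120]
    rr = np.hypot(xx - 60, yy - 60)
    ring = (rr <= 40) & (rr >= 36)
    circle, mask = find_solid_circle(ring)
    assert circle is None and not mask.any()


def test_find_solid_circle_masks_phantom_transducer(lesion_phantom_spec):
    rec = generate_phantom(lesion_phantom_spec)
    result = preprocess_pipeline(rec.pixels, PreprocessParams())
    r0, c0, r1, c1 = result.bbox
    truth = rec.masks["disc"][r0:r1, c0:c1]
    overlap = (result.trace["circle_mask"] & truth).sum() / truth.sum()
    assert overlap >= 0.9


# ---------------------------------------------------------------------------
# local contrast and CIR

def test_local_contrast_constant_zero():
    assert not local_contrast(np.full((6, 6), 77.0)).any()


def test_local_contrast_isolated_peak():
    img = np.zeros((5, 5))
    img[2, 2] = 255.0
    assert local_contrast(img)[2, 2] == pytest.approx(1.0)


def test_local_contrast_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 255, (5, 5))
    assert np.allclose(local_contrast(img), contrast_oracle(img), atol=1e-10)


def test_cir_identity_is_zero():
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 255, (8, 8))
    assert cir(img, img) == pytest.approx(0.0)


def test_cir_constant_original_errors():
    with pytest.raises(ValueError, match="zero local contrast"):
        cir(np.full((8, 8), 100.0), np.random.default_rng(0).uniform(0, 255, (8, 8)))


def test_cir_and_contrast_match_oracles_many_seeds():
    """Vectorized implementations agree with naive double loops (100 seeds)."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 255, (8, 8))
        b = rng.uniform(0, 255, (8, 8))
        assert np.allclose(local_contrast(a), contrast_oracle(a), atol=1e-9)
        assert cir(a, b) == pytest.approx(cir_oracle(a, b), abs=1e-9)


# ---------------------------------------------------------------------------
# top-hat / bottom-hat enhancement

def test_enhance_constant_fixed_point():
    img = np.full((12, 12), 123.0)
    assert np.array_equal(tophat_bothat_enhance(img, 3), img)


def test_enhance_isolated_peak_clips_to_max():
    img = np.full((9, 9), 50.0)
    img[4, 4] = 200.0
    out = tophat_bothat_enhance(img, 1)
    assert out[4, 4] == 255.0


def test_enhance_sign_structure():
    rng = np.random.default_rng(5)
    img = rng.uniform(0, 255, (16, 16))
    se = skmorph.disk(2)
    th = skmorph.white_tophat(img, se)
    bh = skmorph.black_tophat(img, se)
    out = tophat_bothat_enhance(img, 2)
    unclipped = (out > 0) & (out < 255)
    assert (out[(bh == 0) & unclipped] >= img[(bh == 0) & unclipped] - 1e-9).all()
    assert (out[(th == 0) & unclipped] <= img[(th == 0) & unclipped] + 1e-9).all()


def test_enhance_increases_std_on_peaks_and_valleys():
    img = np.full((20, 20), 128.0)
    img[::5, ::5] = 220.0  # isolated peaks
    img[2::5, 2::5] = 30.0  # isolated valleys
    out = tophat_bothat_enhance(img, 2)
    assert out.std() > img.std()


# ---------------------------------------------------------------------------
# SE radius selection

def _phantom_roi(spec):
    rec = generate_phantom(spec)
    result = preprocess_pipeline(rec.pixels, PreprocessParams())
    return result.trace["bbox"]


def test_select_se_radius_zero_tol_equals_exhaustive(normal_spec):
    roi = _phantom_roi(normal_spec)[::2, ::2]
    params = PreprocessParams(se_radii_sweep=tuple(range(1, 9)), cir_rel_tol=0.0)
    best_r, best_cir = select_se_radius(roi, params)
    sweep = {r: cir(roi, tophat_bothat_enhance(roi, r)) for r in range(1, 9)}
    exhaustive = max(sweep, key=lambda r: (sweep[r], -r))
    assert best_r == exhaustive
    assert best_cir == pytest.approx(sweep[exhaustive])
    assert all(best_cir >= v - 1e-12 for v in sweep.values())


def test_select_se_radius_early_stop_never_beats_visited(normal_spec):
    roi = _phantom_roi(normal_spec)[::2, ::2]
    params = PreprocessParams(se_radii_sweep=tuple(range(1, 9)), cir_rel_tol=1e-3)
    best_r, best_cir = select_se_radius(roi, params)
    assert best_cir >= cir(roi, tophat_bothat_enhance(roi, best_r)) - 1e-12


def test_select_se_radius_single_radius():
    rng = np.random.default_rng(2)
    img = rng.uniform(0, 255, (16, 16))
    params = PreprocessParams(se_radii_sweep=(4,))
    assert select_se_radius(img, params)[0] == 4


def test_select_se_radius_constant_errors():
    with pytest.raises(ValueError):
        select_se_radius(np.full((10, 10), 5.0), PreprocessParams(se_radii_sweep=(1, 2)))


# ---------------------------------------------------------------------------
# full pipeline

def test_pipeline_deterministic_and_positive_cir(lesion_phantom_spec):
    rec = generate_phantom(lesion_phantom_spec)
    a = preprocess_pipeline(rec.pixels, PreprocessParams())
    b = preprocess_pipeline(rec.pixels, PreprocessParams())
    assert np.array_equal(a.enhanced, b.enhanced)
    assert a.cir_value > 0
    assert a.chosen_se_radius in PreprocessParams().se_radii_sweep
    assert (a.enhanced >= 0).all() and (a.enhanced <= 255).all()


def test_pipeline_grayscale_input_inpaint_noop(normal_spec):
    rec = generate_phantom(normal_spec)
    gray = rec.pixels[:, :, 0].astype(float)
    result = preprocess_pipeline(gray, PreprocessParams())
    assert not result.trace["mark_mask"].any()
    assert np.array_equal(result.trace["inpainted"], gray)


def test_pipeline_crop_recovers_field(normal_spec):
    rec = generate_phantom(normal_spec)
    result = preprocess_pipeline(rec.pixels, PreprocessParams())
    r0, c0, r1, c1 = result.bbox
    field = rec.masks["field"]
    inside = field[r0:r1, c0:c1].sum()
    assert inside / field.sum() >= 0.99


def test_pipeline_stage_error_names_stage():
    with pytest.raises(PipelineStageError, match="largest_bbox"):
        preprocess_pipeline(np.zeros((20, 20)), PreprocessParams())


def test_sklearn_transformer_roundtrip(normal_spec):
    rec = generate_phantom(normal_spec)
    tf = UltrasoundPreprocessor()
    out = tf.fit_transform([rec.pixels])
    assert len(out) == 1
    assert out[0].ndim == 2
    assert tf.get_params()["params"] is None
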