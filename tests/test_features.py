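"""Feature extractors: GLCM, LTP spectra, wavelet-fractal composites, groups."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

import thermoga as tg
from thermoga.features import (
    GLCM_ANGLES,
    _ANGLE_OFFSETS,
    glcm_descriptors,
    glcm_matrix,
    ltp_polarity_histograms,
    ltp_spectrum_maps,
    quantize,
)


# ---------------------------------------------------------------------------
# GLCM


def brute_force_glcm(q, mask, offset, levels=256):
    """Exhaustive pair enumeration honoring the mask; symmetric, normalized."""
    h, w = q.shape
    counts = np.zeros((levels, levels))
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def test_glcm_constant_roi_degenerate(constant_roi):
    values, names = tg.glcm_features(constant_roi)
    desc = dict(zip(names, values))
    for angle in GLCM_ANGLES:
        assert desc[f"glcm_contrast_a{angle}"] == 0.0
        assert desc[f"glcm_energy_a{angle}"] == 1.0
        # correlation of a zero-variance image is defined as 0
        assert desc[f"glcm_correlation_a{angle}"] == 0.0


def test_glcm_stripes_match_brute_force_oracle():
    # horizontal stripes of two temperature levels
    values = np.where(np.arange(8)[:, None] % 2 == 0, 30.0, 35.0) * np.ones((8, 8))
    roi = tg.RoiMatrix(values=values, mask=None, side="left")
    q = quantize(roi)
    for angle in GLCM_ANGLES:
        expected = brute_force_glcm(q, roi.mask, _ANGLE_OFFSETS[angle])
        got = glcm_matrix(roi, angle)
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_glcm_matches_skimage_on_full_mask(random_roi):
    """Independent oracle: scikit-image co-occurrence on the same levels."""
    q = quantize(random_roi).astype(np.uint8)
    sk = graycomatrix(
        q,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=256,
        symmetric=True,
        normed=True,
    )
    values, names = tg.glcm_features(random_roi)
    desc = dict(zip(names, values))
    for j, angle in enumerate(GLCM_ANGLES):
        np.testing.assert_allclose(
            glcm_matrix(random_roi, angle), sk[:, :, 0, j], atol=1e-12
        )
        for prop in ("contrast", "dissimilarity", "homogeneity", "energy", "ASM"):
            assert desc[f"glcm_{prop.lower()}_a{angle}"] == pytest.approx(
                float(graycoprops(sk, prop)[0, j]), rel=1e-9
            )
        assert desc[f"glcm_correlation_a{angle}"] == pytest.approx(
            float(graycoprops(sk, "correlation")[0, j]), abs=1e-9
        )


def test_glcm_respects_mask():
    rng = np.random.default_rng(2)
    values = 33.0 + rng.standard_normal((12, 12))
    mask = np.ones((12, 12), dtype=bool)
    mask[:, 6:] = False
    mask[0, 0] = False
    roi = tg.RoiMatrix(values=values, mask=mask, side="left")
    q = quantize(roi)
    for angle in GLCM_ANGLES:
        expected = brute_force_glcm(q, mask, _ANGLE_OFFSETS[angle])
        np.testing.assert_allclose(glcm_matrix(roi, angle), expected, atol=1e-12)


def test_glcm_output_contract(random_roi):
    values, names = tg.glcm_features(random_roi)
    assert len(values) == 24 and len(names) == 24
    # deterministic order: angle-major, six descriptors each
    assert names[0] == "glcm_contrast_a0" and names[-1] == "glcm_asm_a135"
    values2, names2 = tg.glcm_features(random_roi)
    np.testing.assert_array_equal(values, values2)


def test_glcm_matrix_is_symmetric_and_normalized(random_roi):
    for angle in GLCM_ANGLES:
        p = glcm_matrix(random_roi, angle)
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T, atol=1e-15)


# ---------------------------------------------------------------------------
# LTP spectra


def test_ltp_constant_roi_all_spectrum_zero(constant_roi):
    maps = ltp_spectrum_maps(constant_roi)
    interior = 14 * 14
    assert maps[0].sum() == interior
    assert all(m.sum() == 0 for m in maps[1:])


def test_ltp_cold_center_pixel_in_spectrum_eight():
    values = np.full((5, 5), 33.0)
    values[2, 2] = 30.0  # colder than all 8 neighbors by >> t
    roi = tg.RoiMatrix(values=values, mask=None, side="left")
    maps = ltp_spectrum_maps(roi, t=0.1)
    assert maps[8][2, 2] == 1
    assert maps[8].sum() == 1


def test_ltp_maps_partition_interior(random_roi):
    maps = ltp_spectrum_maps(random_roi)
    interior = np.zeros(random_roi.shape, dtype=bool)
    interior[1:-1, 1:-1] = random_roi.mask[1:-1, 1:-1]
    total = sum(int(m.sum()) for m in maps)
    assert total == int(interior.sum())
    # each interior pixel in exactly one map
    stack = np.sum([m.astype(int) for m in maps], axis=0)
    assert np.array_equal(stack > 0, interior)
    assert stack.max() == 1


def test_ltp_differences_below_threshold_are_neutral():
    rng = np.random.default_rng(0)
    values = 33.0 + 0.01 * rng.standard_normal((10, 10))  # all within t=0.1
    roi = tg.RoiMatrix(values=values, mask=None, side="left")
    maps = ltp_spectrum_maps(roi, t=0.1)
    assert maps[0].sum() == 8 * 8


def test_ltp_rejects_tiny_roi():
    # RoiMatrix requires >= 16 cells, so use a 16x1-shaped invalid grid
    roi = tg.RoiMatrix(values=np.full((16, 2), 33.0), mask=None, side="left")
    with pytest.raises(ValueError, match="3x3"):
        ltp_spectrum_maps(roi)


def test_ltp_histograms_are_frequencies(random_roi):
    values, names = ltp_polarity_histograms(random_roi)
    assert len(values) == 50
    upper = values[:25]
    lower = values[25:]
    assert upper.sum() == pytest.approx(1.0)
    assert lower.sum() == pytest.approx(1.0)
    assert names[0].startswith("ltphist_upper") and names[-1].startswith("ltphist_lower")


# ---------------------------------------------------------------------------
# groups


@pytest.mark.parametrize(
    "name,length",
    [
        ("fractals_wavelets_8ltp", 384),
        ("fractals_8ltp", 48),
        ("glcm", 48),
        ("fractals_2ltp_glcm", 60),
        ("fractals_3ltp", 18),
        ("glcm_8ltp", 148),
    ],
)
def test_group_dimensionalities(roi_pair, name, length):
    fv = tg.compute_group(roi_pair, name)
    assert len(fv.values) == length
    assert len(set(fv.column_names)) == length
    assert np.all(np.isfinite(fv.values))


def test_group_glcm_8ltp_composition(roi_pair):
    fv = tg.compute_group(roi_pair, "glcm_8ltp")
    n_ltp = sum("ltphist" in c for c in fv.column_names)
    n_glcm = sum("glcm" in c for c in fv.column_names)
    assert n_ltp == 100 and n_glcm == 48


def test_group_concatenates_left_then_right(roi_pair):
    fv = tg.compute_group(roi_pair, "fractals_3ltp")
    assert all(c.startswith("left_") for c in fv.column_names[:9])
    assert all(c.startswith("right_") for c in fv.column_names[9:])


def test_group_determinism(roi_pair):
    a = tg.compute_group(roi_pair, "fractals_wavelets_8ltp")
    b = tg.compute_group(roi_pair, "fractals_wavelets_8ltp")
    assert a.values.tobytes() == b.values.tobytes()
    assert a.column_names == b.column_names


def test_wavelet_fractal_constant_roi_petrosian_sentinels(constant_roi):
    values, names = tg.wavelet_fractal_features(constant_roi)
    assert len(values) == 192
    petro = [v for v, n in zip(values, names) if n.endswith("petrosian")]
    assert len(petro) == 64
    assert all(p == 1.0 for p in petro)


def test_unknown_group_and_bad_spectrum_rejected(roi_pair):
    with pytest.raises(ValueError, match="unknown feature group"):
        tg.compute_group(roi_pair, "no_such_group")
    bad = tg.FeatureGroup.from_components("bad", [("ltp_fractal", (0, 9))])
    with pytest.raises(ValueError, match="undefined LTP spectrum"):
        tg.compute_group(roi_pair, bad)


def test_extract_table_contract(roi_pair):
    spec = tg.SynthSpec(n_exams=4, image_shape=(32, 32), seed=9)
    pairs = tg.make_roi_pairs(spec)
    data = tg.extract_table(pairs, "fractals_3ltp")
    assert data.features.shape == (4, 18)
    assert data.exam_ids == tuple(p.exam_id for p in pairs)
    data2 = tg.extract_table(pairs, "fractals_3ltp")
    np.testing.assert_array_equal(data.features, data2.features)
    with pytest.raises(ValueError, match="empty"):
        tg.extract_table([], "fractals_3ltp")
    unlabeled = tg.RoiPair(
        left=pairs[0].left, right=pairs[0].right, label=None, exam_id="x"
    )
    with pytest.raises(ValueError, match="label"):
        tg.extract_table([unlabeled], "fractals_3ltp")
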