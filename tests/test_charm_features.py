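import numpy as np
import pytest
from scipy import stats

from phenoprobe.charm_features import (
    FAMILIES,
    N_FEATURES,
    extract_charm,
    extract_family,
    family_length,
    feature_manifest,
    feature_names,
    plane_family_grid,
    transform_stack,
    zernike_magnitudes,
)
from phenoprobe.synthetic_screen import PhenotypeSpec, render_field


@pytest.fixture(scope="module")
def random_image():
    return np.random.default_rng(42).random((96, 96))


def test_manifest_has_923_unique_stable_names():
    mf = feature_manifest()
    assert len(mf) == N_FEATURES
    assert mf["feature_name"].is_unique
    assert feature_names() == mf["feature_name"].tolist()
    total = sum(family_length(f) for _, f in plane_family_grid())
    assert total == N_FEATURES


def test_extract_charm_returns_923_finite_values(random_image):
    v = extract_charm(random_image)
    assert v.shape == (N_FEATURES,)
    assert np.isfinite(v).all()


def test_extract_charm_is_deterministic(random_image):
    assert np.array_equal(extract_charm(random_image),
                          extract_charm(random_image))


def test_transform_stack_planes_present_and_2d(random_image):
    planes = transform_stack(random_image)
    assert set(planes) == {
        "raw", "fourier", "wavelet", "chebyshev", "edge",
        "wavelet_of_fourier", "fourier_of_wavelet", "chebyshev_of_fourier"}
    for plane in planes.values():
        assert plane.ndim == 2
        assert plane.min() >= 0.0 and plane.max() <= 1.0


def test_transform_stack_constant_image_degenerates_cleanly():
    planes = transform_stack(np.full((64, 64), 0.7))
    # DC term is removed before the magnitude, so the plane is all zero
    assert not planes["fourier"].any()
    assert not planes["edge"].any()


def test_transform_stack_rejects_bad_input():
    with pytest.raises(ValueError):
        transform_stack(np.zeros((3, 64, 64)))
    with pytest.raises(ValueError):
        transform_stack(np.zeros((32, 32)))
    bad = np.zeros((64, 64))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        transform_stack(bad)


def test_unknown_family_lists_valid_names(random_image):
    with pytest.raises(ValueError, match="haralick"):
        extract_family(random_image, "not_a_family")


def test_haralick_of_constant_plane():
    v = extract_family(np.full((64, 64), 0.5), "haralick")
    # single grey level: angular second moment 1, contrast 0 (all angles)
    asm_avg, contrast_avg = v[0], v[1]
    assert asm_avg == pytest.approx(1.0)
    assert contrast_avg == pytest.approx(0.0)


def test_multiscale_histogram_entropy_zero_on_constant():
    v = extract_family(np.full((64, 64), 0.3), "multiscale_histograms")
    # entropy is the last feature of each scale block
    idx = 0
    for bins in (2, 4, 6, 8):
        block = v[idx:idx + bins + 1]
        assert block[-1] == pytest.approx(0.0)
        assert block[:-1].sum() == pytest.approx(1.0)
        idx += bins + 1


@pytest.mark.parametrize("family", FAMILIES)
def test_every_family_has_fixed_length_finite_output(random_image, family):
    v = extract_family(random_image, family)
    assert v.shape == (family_length(family),)
    assert np.isfinite(v).all()


def _disk_image(size=96, radius=20, offset=(0, 0), value=0.5, bg=0.1):
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    img = np.full((size, size), bg)
    img[(yy - c - offset[0]) ** 2 + (xx - c - offset[1]) ** 2 <= radius**2] = value
    return img


def test_zernike_magnitudes_invariant_to_90_degree_rotation():
    img = _disk_image(offset=(8, 3))  # off-centre: nontrivial angular content
    v0 = extract_family(img, "zernike")
    v90 = extract_family(np.rot90(img), "zernike")
    assert np.allclose(v0, v90, atol=1e-6)


def test_haralick_direction_average_invariant_to_90_degree_rotation():
    rng = np.random.default_rng(3)
    img = rng.random((80, 80))
    v0 = extract_family(img, "haralick")[:13]
    v90 = extract_family(np.rot90(img), "haralick")[:13]
    assert np.allclose(v0, v90, atol=1e-6)


def test_zernike_on_raw_mask_matches_direct_call():
    img = _disk_image()
    mask = img > 0.3
    direct = zernike_magnitudes(mask)
    assert np.allclose(extract_family(img, "zernike"), direct)


def test_intensity_shift_moves_mean_but_not_thresholded_shape():
    """A clipped brightness shift changes intensity statistics but leaves
    the Zernike signature of the thresholded object intact."""
    img = _disk_image(value=0.5, bg=0.1)
    img[10:14, 10:14] = 0.95  # third grey level so clipping reshapes the
    shifted = np.clip(img + 0.1, 0, 1)  # distribution after stretching
    names = feature_names()
    v0, v1 = extract_charm(img), extract_charm(shifted)
    mean_idx = names.index("raw|pixel_stats|mean")
    assert v0[mean_idx] != pytest.approx(v1[mean_idx], abs=1e-9)
    zidx = [i for i, n in enumerate(names) if n.startswith("raw|zernike|")]
    assert np.allclose(v0[zidx], v1[zidx], atol=1e-3)


def test_no_stain_and_diffuse_classes_separate_in_pixel_stats():
    """Basic sanity: the bank distinguishes blank from stained images."""
    diffuse, blank = [], []
    for seed in range(20):
        d = render_field(PhenotypeSpec(), cells=5, size=64, seed=seed)
        b = render_field(PhenotypeSpec(stain_class="no_stain",
                                       artifact_rate=2.0),
                         cells=5, size=64, seed=seed)
        diffuse.append(extract_family(transform_stack(d[1])["raw"],
                                      "pixel_stats"))
        blank.append(extract_family(transform_stack(b[1])["raw"],
                                    "pixel_stats"))
    diffuse, blank = np.array(diffuse), np.array(blank)
    pvals = [stats.mannwhitneyu(diffuse[:, j], blank[:, j]).pvalue
             for j in range(diffuse.shape[1])]
    assert min(pvals) < 1e-4
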