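"""Unit and property tests for the low-level image operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfinject import vision
from zfinject.vision import (DegenerateHistogramError, InvalidImageError,
                             StructElement, binarize, compute_histogram,
                             dilate, excessive_dilate, max_entropy_threshold,
                             particle_filter, to_grayscale)

from conftest import brute_force_kapur, naive_dilate


# ------------------------------------------------------------- grayscale

@pytest.mark.parametrize("pixel,expected", [
    ((30, 60, 90), 60),     # exact integer mean
    ((255, 255, 255), 255), # already gray
    ((0, 0, 1), 0),         # 1/3 floors to 0
    ((10, 10, 12), 10),     # 32/3 = 10.67 floors to 10
])
def test_grayscale_mean_with_floor(pixel, expected):
    img = np.array([[pixel]], dtype=np.uint8)
    assert to_grayscale(img, rounding="floor")[0, 0] == expected


def test_grayscale_rounding_modes_and_shape(rng):
    img = rng.integers(0, 256, (17, 23, 3), dtype=np.uint8)
    floor = to_grayscale(img, "floor")
    near = to_grayscale(img, "nearest")
    exact = to_grayscale(img, "exact")
    assert floor.shape == near.shape == (17, 23)
    assert np.all(np.abs(near.astype(int) - exact) <= 0.5 + 1e-9)
    assert np.all(floor == np.floor(exact))


def test_grayscale_rejects_empty_and_malformed():
    with pytest.raises(InvalidImageError):
        to_grayscale(np.zeros((0, 5, 3), dtype=np.uint8))
    with pytest.raises(InvalidImageError):
        to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


# ------------------------------------------------------------- histogram

def test_histogram_counts_and_conservation(rng):
    img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
    h = compute_histogram(img)
    assert h[0] == 2 and h[255] == 2 and h.sum() == 4

    img = rng.integers(0, 256, (64, 64), dtype=np.uint8)
    h = compute_histogram(img)
    assert h.sum() == 64 * 64
    v = int(img[5, 5])
    assert h[v] == np.count_nonzero(img == v)


# ------------------------------------------- maximum-entropy thresholding

def test_uniform_histogram_threshold_is_midpoint():
    # equal counts in all 256 bins: Hsum(k) = ln(k+1) + ln(255-k), peak at 127
    scan = max_entropy_threshold(np.full(256, 10))
    assert scan.K == 127


def test_four_level_toy_histogram():
    # exhaustive check: 2*ln2 at k=1 beats ln3 at k=0 and k=2
    scan = max_entropy_threshold(np.array([1, 1, 1, 1]))
    assert scan.K == 1
    assert scan.Hsum[1] == pytest.approx(2 * np.log(2))
    assert scan.Hsum[0] == pytest.approx(np.log(3))


def test_two_spike_histogram_tie_breaks_low():
    h = np.zeros(256, dtype=int)
    h[10] = 40
    h[200] = 60
    scan = max_entropy_threshold(h)
    # Hsum is identically 0 on every valid k; smallest k wins
    assert scan.K == 10
    assert np.allclose(scan.Hsum[scan.valid], 0.0, atol=1e-12)


def test_degenerate_histogram_names_the_bin():
    h = np.zeros(256, dtype=int)
    h[42] = 1000
    with pytest.raises(DegenerateHistogramError) as exc:
        max_entropy_threshold(h)
    assert exc.value.bin_index == 42
    assert "42" in str(exc.value)


def test_scan_probability_invariants(rng):
    h = rng.integers(0, 50, 256)
    h[0] += 1  # ensure nonempty
    h[255] += 1
    scan = max_entropy_threshold(h)
    assert scan.p.sum() == pytest.approx(1.0, abs=1e-12)
    valid = scan.valid
    assert np.all(np.abs(scan.P0[valid] + scan.P1[valid] - 1.0) < 1e-12)
    assert np.allclose(scan.Hsum[valid], scan.H0[valid] + scan.H1[valid])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(0, 30), min_size=4, max_size=64))
def test_threshold_matches_brute_force(counts):
    counts = np.asarray(counts)
    occupied = np.count_nonzero(counts)
    if occupied == 0:
        with pytest.raises(ValueError):
            max_entropy_threshold(counts)
    elif occupied == 1:
        with pytest.raises(DegenerateHistogramError):
            max_entropy_threshold(counts)
    else:
        assert max_entropy_threshold(counts).K == brute_force_kapur(counts)


# -------------------------------------------------------------- binarize

def test_binarize_rule_and_polarities():
    img = np.array([[10, 200]], dtype=np.uint8)
    assert binarize(img, 100, "bright").tolist() == [[0, 1]]
    assert binarize(img, 100, "inverted").tolist() == [[1, 0]]
    assert binarize(img, 255, "bright").sum() == 0


def test_binarize_boundary_pixel_is_background():
    img = np.array([[100]], dtype=np.uint8)
    assert binarize(img, 100, "bright")[0, 0] == 0  # <= K is background


def test_binarize_complement_equals_inverted(rng):
    img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
    k = int(rng.integers(0, 255))
    assert np.array_equal(1 - binarize(img, k, "bright"), binarize(img, k, "inverted"))


def test_binarize_auto_picks_minority_class():
    img = np.zeros((10, 10), dtype=np.uint8)
    img[:2, :2] = 200  # bright minority
    assert binarize(img, 100, "auto").sum() == 4
    img2 = np.full((10, 10), 200, dtype=np.uint8)
    img2[:2, :2] = 10  # dark minority
    assert binarize(img2, 100, "auto").sum() == 4


# ------------------------------------------------------- particle filter

def test_particle_filter_removes_small_specks(rng):
    img = np.zeros((40, 40), dtype=np.uint8)
    img[5:15, 5:15] = 1  # 100 px blob
    img[30, 30] = img[35, 2] = img[2, 35] = 1
    img[30, 31] = 1
    out = particle_filter(img, min_area=10)
    assert out.sum() == 100
    assert particle_filter(img, min_area=0).sum() == img.sum()


def test_particle_filter_idempotent_and_oracle(rng):
    img = (rng.random((48, 48)) < 0.25).astype(np.uint8)
    once = particle_filter(img, min_area=5)
    assert np.array_equal(once, particle_filter(once, min_area=5))
    # min_area above the largest component empties the image
    from scipy import ndimage
    lab, n = ndimage.label(img, structure=np.ones((3, 3)))
    max_area = np.bincount(lab.ravel())[1:].max() if n else 0
    assert particle_filter(img, min_area=int(max_area) + 1).sum() == 0


def test_particle_filter_connectivity_matters():
    img = np.zeros((6, 6), dtype=np.uint8)
    img[1, 1] = img[2, 2] = img[3, 3] = 1  # diagonal chain
    assert particle_filter(img, min_area=3, connectivity=8).sum() == 3
    assert particle_filter(img, min_area=3, connectivity=4).sum() == 0


# -------------------------------------------------------------- dilation

def test_dilate_single_pixel_full_3x3():
    img = np.zeros((5, 5), dtype=np.uint8)
    img[2, 2] = 1
    out = dilate(img, StructElement.square(3))
    assert out.sum() == 9 and out[1:4, 1:4].all()


def test_dilate_empty_stays_empty():
    img = np.zeros((8, 8), dtype=np.uint8)
    assert dilate(img, StructElement.square(9)).sum() == 0


def test_dilate_matches_naive_oracle(rng):
    for _ in range(5):
        img = (rng.random((32, 32)) < 0.15).astype(np.uint8)
        mask = rng.random((3, 3)) < 0.7
        mask[1, 1] = True
        se = StructElement(mask)
        assert np.array_equal(dilate(img, se), naive_dilate(img, se.mask))


def test_dilation_extensive_and_monotone(rng):
    x = (rng.random((30, 30)) < 0.2).astype(np.uint8)
    y = np.clip(x + (rng.random((30, 30)) < 0.1), 0, 1).astype(np.uint8)
    se = StructElement.square(5)
    dx, dy = dilate(x, se), dilate(y, se)
    assert np.all(dx >= x)            # extensivity
    assert np.all(dy >= dx)           # monotonicity (x subset y)


def test_excessive_dilate_growth_and_identity():
    img = np.zeros((201, 201), dtype=np.uint8)
    img[100, 100] = 1
    out = excessive_dilate(img, se_size=9, iterations=11)
    # Chebyshev growth of 4 px per iteration: 89 x 89 square
    assert out.sum() == 89 * 89
    rows = np.nonzero(out.any(axis=1))[0]
    assert rows.min() == 100 - 44 and rows.max() == 100 + 44
    assert np.array_equal(excessive_dilate(img, 9, 0), img)


def test_excessive_dilate_preserves_centroid_of_disc():
    img = np.zeros((301, 301), dtype=np.uint8)
    rr, cc = np.ogrid[:301, :301]
    img[(rr - 150) ** 2 + (cc - 150) ** 2 <= 40**2] = 1
    out = excessive_dilate(img, 9, 11)
    before = np.argwhere(img).mean(axis=0)
    after = np.argwhere(out).mean(axis=0)
    assert np.hypot(*(after - before)) <= 0.5


def test_struct_element_validation():
    with pytest.raises(ValueError):
        StructElement(np.ones((4, 4)))
    with pytest.raises(ValueError):
        StructElement(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        StructElement.square(2)
    assert vision.dilation_growth(9, 11) == 44
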