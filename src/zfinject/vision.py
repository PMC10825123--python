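"""Low-level image operators for brightfield zebrafish localization.

The pipeline segments a single embryo or larva from a brightfield frame:
mean-value graying, histogramming, maximum-entropy (Kapur-style) automatic
thresholding, binarization, connected-component area filtering of binary
noise, and iterated ("excessive") morphological dilation that closes the
foreground holes left by the transparent larval body.

All images are numpy arrays: color images are ``(H, W, 3)`` uint8, grayscale
``(H, W)`` uint8, binary ``(H, W)`` of {0, 1} (uint8 or bool). Coordinates
are 0-based with row = y (downward) and column = x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class InvalidImageError(ValueError):
    """Raised when an input image is empty or malformed."""


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has a single occupied bin, so no threshold
    can split the image into two nonempty classes."""

    def __init__(self, bin_index: int):
        self.bin_index = int(bin_index)
        super().__init__(
            f"degenerate histogram: all mass in grayscale bin {bin_index}; "
            "no threshold separates two nonempty classes"
        )


def _as_image(img, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != ndim or arr.size == 0:
        raise InvalidImageError(f"{name}: expected nonempty {ndim}-D array, got shape {arr.shape}")
    return arr


def to_grayscale(img: np.ndarray, rounding: str = "floor") -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale by the mean-value method.

    Each output pixel is ``(R + G + B) / 3``.  The exact mean is generally
    not an integer; ``rounding`` selects how it is mapped to 8 bits:
    ``"floor"`` (default) truncates, ``"nearest"`` rounds half away from
    zero, ``"exact"`` returns float64 without quantization.
    """
    arr = _as_image(img, 3, "color image")
    if arr.shape[2] != 3:
        raise InvalidImageError(f"color image must have 3 channels, got {arr.shape[2]}")
    mean = arr.astype(np.float64).sum(axis=2) / 3.0
    if rounding == "floor":
        return np.floor(mean).astype(np.uint8)
    if rounding == "nearest":
        # round-half-away-from-zero, matching fixed-point hardware convention
        return np.floor(mean + 0.5).astype(np.uint8)
    if rounding == "exact":
        return mean
    raise ValueError(f"unknown rounding mode {rounding!r}")


def compute_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin grayscale histogram: ``counts[i]`` = number of pixels of value i."""
    arr = _as_image(img, 2, "gray image")
    if arr.dtype.kind == "f":
        arr = np.clip(np.floor(arr), 0, 255)
    return np.bincount(arr.astype(np.intp).ravel(), minlength=256)


@dataclass
class ThresholdScan:
    """Full audit trail of a maximum-entropy threshold scan.

    Arrays are indexed by candidate threshold k; entries are NaN where k is
    invalid (one of the two classes would be empty).  ``K`` is the selected
    threshold: the smallest k maximizing ``Hsum``.
    """

    p: np.ndarray
    P0: np.ndarray
    P1: np.ndarray
    H0: np.ndarray
    H1: np.ndarray
    Hsum: np.ndarray
    K: int
    valid: np.ndarray = field(repr=False, default=None)


def max_entropy_threshold(hist: np.ndarray) -> ThresholdScan:
    """Select the grayscale threshold maximizing total class entropy.

    The histogram is normalized to probabilities p_i.  For each candidate
    threshold k, pixels with value <= k form the background class (mass P0)
    and the rest the foreground (mass P1 = 1 - P0).  The Shannon entropies
    of the two normalized class distributions,

        H0(k) = -sum_{i<=k} (p_i/P0) ln(p_i/P0)
        H1(k) = -sum_{i>k}  (p_i/P1) ln(p_i/P1)

    are summed and the k maximizing H0 + H1 is returned (ties break toward
    the smallest k).  Terms with p_i = 0 contribute zero; candidates where
    either class is empty are excluded.

    Works on histograms of any length >= 2, not only 256 bins.
    """
    counts = np.asarray(hist, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1-D array with at least 2 bins")
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty (total count is zero)")

    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        raise DegenerateHistogramError(occupied[0])

    p = counts / total
    P0 = np.cumsum(p)
    P1 = 1.0 - P0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    # s(k) = -sum_{i<=k} p_i ln p_i; Kapur's identity gives
    # H0 = ln P0 + s/P0 and H1 = ln P1 + (s_tot - s)/P1.
    s = -np.cumsum(plogp)
    s_tot = s[-1]

    valid = (P0 > 0) & (P1 > 0)
    # guard P1 against negative rounding residue on the last valid bins
    P1 = np.maximum(P1, 0.0)
    n = counts.size
    H0 = np.full(n, np.nan)
    H1 = np.full(n, np.nan)
    idx = np.nonzero(valid)[0]
    H0[idx] = np.log(P0[idx]) + s[idx] / P0[idx]
    H1[idx] = np.log(P1[idx]) + (s_tot - s[idx]) / P1[idx]
    Hsum = H0 + H1

    scores = np.where(valid, Hsum, -np.inf)
    K = int(np.argmax(scores))  # argmax takes the first (smallest) maximizer
    return ThresholdScan(p=p, P0=P0, P1=P1, H0=H0, H1=H1, Hsum=Hsum, K=K, valid=valid)


def binarize(img: np.ndarray, K: int, polarity: str = "bright") -> np.ndarray:
    """Threshold a grayscale image into a {0,1} binary image.

    ``polarity="bright"`` keeps the brightfield convention: pixels <= K are
    background (0), pixels > K foreground (1).  ``"inverted"`` swaps the
    classes for dark-on-bright acquisitions.  ``"auto"`` picks whichever
    class is the minority as foreground, since the sample occupies a small
    fraction of the field of view.
    """
    arr = _as_image(img, 2, "gray image")
    if not 0 <= K <= 255:
        raise ValueError(f"threshold K={K} outside [0, 255]")
    fg = (arr > K).astype(np.uint8)
    if polarity == "bright":
        return fg
    if polarity == "inverted":
        return 1 - fg
    if polarity == "auto":
        return fg if fg.sum() * 2 <= fg.size else 1 - fg
    raise ValueError(f"unknown polarity {polarity!r}")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def particle_filter(img: np.ndarray, min_area: int, connectivity: int = 8) -> np.ndarray:
    """Low-pass filter binary noise: remove foreground components smaller
    than ``min_area`` pixels.  Components of area >= min_area pass unchanged,
    so the operation is idempotent at a fixed ``min_area``.
    """
    arr = _as_image(img, 2, "binary image")
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area <= 1:
        return arr.astype(np.uint8).copy()
    labels, n = ndimage.label(arr != 0, structure=_connectivity_structure(connectivity))
    if n == 0:
        return np.zeros_like(arr, dtype=np.uint8)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels].astype(np.uint8)


@dataclass(frozen=True)
class StructElement:
    """Odd-sized square structuring element anchored at its center."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 2 == 0:
            raise ValueError("structuring element must be an odd-sized square")
        if not np.any(m):
            raise ValueError("structuring element must contain at least one 1-cell")
        object.__setattr__(self, "mask", m != 0)

    @property
    def size(self) -> int:
        return self.mask.shape[0]

    @classmethod
    def square(cls, size: int) -> "StructElement":
        """All-ones size x size element (the default 9 x 9 used for larvae)."""
        if size < 1 or size % 2 == 0:
            raise ValueError("size must be odd and >= 1")
        return cls(np.ones((size, size), dtype=bool))


def dilate(img: np.ndarray, se: StructElement) -> np.ndarray:
    """Binary dilation: each output pixel is the maximum of its input
    neighborhood under the structuring element (borders pad with background).

    The neighborhood-maximum form is the operational definition; for the
    symmetric elements used throughout it coincides with the Minkowski sum
    S = X (+) B.
    """
    arr = _as_image(img, 2, "binary image")
    out = ndimage.maximum_filter((arr != 0).astype(np.uint8),
                                 footprint=se.mask, mode="constant", cval=0)
    return out.astype(np.uint8)


def excessive_dilate(img: np.ndarray, se_size: int = 9, iterations: int = 11) -> np.ndarray:
    """Iterated dilation with a full square element.

    Defaults (9 x 9 element, 11 iterations) grow each foreground pixel by 44
    in Chebyshev distance — enough to close the transparency holes in a
    binarized larval body while leaving the centroid of a symmetric contour
    unchanged.  ``iterations=0`` is the identity.
    """
    arr = _as_image(img, 2, "binary image")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return arr.astype(np.uint8).copy()
    se = StructElement.square(se_size)
    out = ndimage.binary_dilation(arr != 0, structure=se.mask, iterations=iterations)
    return out.astype(np.uint8)


def dilation_growth(se_size: int = 9, iterations: int = 11) -> int:
    """Chebyshev radius gained by ``excessive_dilate``: (se_size // 2) * iterations."""
    return (se_size // 2) * iterations
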