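"""Particle analysis, circle detection, and target selection.

Produces the injection target: the center of a zebrafish embryo, or the
center of the yolk of a larva — the largest near-circular structure in the
segmented frame.  ``detect_sample`` chains the full recognition pipeline
from a color frame to the target point C.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _sk_perimeter
from skimage.transform import hough_circle, hough_circle_peaks

from . import vision
from .vision import DegenerateHistogramError, _as_image, _connectivity_structure


@dataclass(frozen=True)
class Particle:
    """One connected foreground component.

    ``bbox`` is (row_min, col_min, row_max, col_max), inclusive on both ends;
    ``centroid`` is the (row, col) mean of member pixels.
    """

    label: int
    area: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]


@dataclass(frozen=True)
class DetectedCircle:
    center: tuple[float, float]  # (row, col)
    radius: float
    score: float  # fit quality in [0, 1]


@dataclass
class DetectionResult:
    particles: list[Particle]
    circles: list[DetectedCircle]
    roi: Particle | None
    target: tuple[float, float] | None
    success: bool
    stage_images: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class DetectionConfig:
    """Recognition-pipeline parameters.

    Morphology defaults (9 x 9 element, 11 iterations) are the excessive-
    dilation setting that closes larval transparency holes.  ``radius_range``
    bounds the acceptable target radius in *pre-dilation* pixels; the
    pipeline widens it by the dilation growth internally, since no camera
    calibration is assumed.
    """

    rounding: str = "floor"
    polarity: str = "bright"
    min_area: int = 50
    connectivity: int = 8
    se_size: int = 9
    iterations: int = 11
    radius_range: tuple[int, int] = (12, 120)
    circle_method: str = "inscribed"
    circularity_threshold: float = 0.6
    keep_stages: bool = False


def particle_analysis(img: np.ndarray, connectivity: int = 8) -> list[Particle]:
    """Label connected foreground components and measure area/bbox/centroid."""
    arr = _as_image(img, 2, "binary image")
    labels, n = ndimage.label(arr != 0, structure=_connectivity_structure(connectivity))
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index).astype(int)
    centroids = ndimage.center_of_mass(arr != 0, labels, index)
    slices = ndimage.find_objects(labels)
    out = []
    for lab, area, cen, sl in zip(index, areas, centroids, slices):
        bbox = (sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1)
        out.append(Particle(label=int(lab), area=int(area), bbox=bbox,
                            centroid=(float(cen[0]), float(cen[1]))))
    return out


def _circle_sort_key(c: DetectedCircle):
    return (-c.radius, -c.score, c.center[0], c.center[1])


def _component_circularity(mask: np.ndarray) -> float:
    area = int(mask.sum())
    per = _sk_perimeter(mask, neighborhood=8)
    if per <= 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / per**2))


def _inscribed_circles(arr, radius_range, connectivity):
    """Largest inscribed circle of each component via the Euclidean distance
    transform.  The EDT peak is the incenter; with a heavily dilated blob it
    sits exactly where the pre-dilation structure was widest (the yolk), so
    this detector is insensitive to the contour distortion that iterated
    square-element dilation introduces."""
    labels, n = ndimage.label(arr != 0, structure=_connectivity_structure(connectivity))
    circles = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        mask = np.pad(labels[sl] == lab, 1)
        dist = ndimage.distance_transform_edt(mask)
        radius = float(dist.max())
        if not radius_range[0] <= radius <= radius_range[1]:
            continue
        # sub-pixel center: centroid of the near-maximal plateau.  A window
        # of a few px averages out the noise-induced bumps that would
        # otherwise yank the argmax along the flat ridge a dilated
        # body+yolk union produces.
        plateau = np.nonzero(dist >= radius - 2.5)
        center = (float(plateau[0].mean() - 1 + sl[0].start),
                  float(plateau[1].mean() - 1 + sl[1].start))
        circles.append(DetectedCircle(center=center, radius=radius,
                                      score=_component_circularity(mask)))
    return circles


def _hough_circles(arr, radius_range, connectivity, circularity_threshold):
    """Circular Hough transform on component boundaries, with a circularity
    fallback (centroid + equivalent radius) for components the accumulator
    misses.  Suited to undilated frames where contours are true circles."""
    mask = arr != 0
    edges = mask & ~ndimage.binary_erosion(mask, border_value=0)
    lo, hi = int(radius_range[0]), int(radius_range[1])
    radii = np.arange(max(1, lo), max(1, hi) + 1)
    circles: list[DetectedCircle] = []
    if edges.any() and radii.size:
        accum = hough_circle(edges, radii, normalize=True)
        accums, cols, rows, rads = hough_circle_peaks(
            accum, radii, total_num_peaks=8,
            min_xdistance=max(2, lo), min_ydistance=max(2, lo))
        for support, r, c, rad in zip(accums, rows, cols, rads):
            # normalized accumulator ~ supported fraction of the circumference
            if support < 0.25:
                continue
            circles.append(DetectedCircle(center=(float(r), float(c)),
                                          radius=float(rad),
                                          score=float(min(1.0, support))))
    if not circles:
        # fallback: round-enough components become circles outright
        for p in particle_analysis(arr, connectivity):
            sl = (slice(p.bbox[0], p.bbox[2] + 1), slice(p.bbox[1], p.bbox[3] + 1))
            sub = np.asarray(arr[sl] != 0)
            circ = _component_circularity(np.pad(sub, 1))
            if circ >= circularity_threshold:
                radius = float(np.sqrt(p.area / np.pi))
                if radius_range[0] <= radius <= radius_range[1]:
                    circles.append(DetectedCircle(center=p.centroid, radius=radius, score=circ))
    return circles


def detect_circles(img: np.ndarray, radius_range: tuple[float, float],
                   method: str = "inscribed", connectivity: int = 8,
                   circularity_threshold: float = 0.6) -> list[DetectedCircle]:
    """Find circular structures in a binary image, largest radius first.

    ``method="inscribed"`` (default) reports the largest inscribed circle of
    each foreground component; ``"hough"`` runs a circular Hough transform on
    component boundaries with a contour-circularity fallback.
    """
    arr = _as_image(img, 2, "binary image")
    if radius_range[0] < 1:
        raise ValueError("minimum radius must be >= 1 px")
    if method == "inscribed":
        circles = _inscribed_circles(arr, radius_range, connectivity)
    elif method == "hough":
        circles = _hough_circles(arr, radius_range, connectivity, circularity_threshold)
    else:
        raise ValueError(f"unknown circle-detection method {method!r}")
    return sorted(circles, key=_circle_sort_key)


def select_target(particles: list[Particle],
                  circles: list[DetectedCircle]) -> DetectionResult:
    """Apply the target-selection rules.

    The region of interest is the particle of maximal area (anti-interference:
    debris components are smaller than the sample).  The target point C is
    the center of the largest-radius circle; if that center falls outside the
    ROI bounding box, the largest circle inside the ROI is used instead.
    Missing particles or circles yield an unsuccessful (but valid) result.
    """
    roi = None
    if particles:
        roi = min(particles, key=lambda p: (-p.area, p.label))
    ordered = sorted(circles, key=_circle_sort_key)

    target = None
    if roi is not None and ordered:
        def inside(c):
            r0, c0, r1, c1 = roi.bbox
            return r0 <= c.center[0] <= r1 and c0 <= c.center[1] <= c1
        chosen = ordered[0] if inside(ordered[0]) else next((c for c in ordered if inside(c)), None)
        if chosen is not None:
            target = chosen.center
    return DetectionResult(particles=list(particles), circles=ordered,
                           roi=roi, target=target, success=target is not None)


def detect_sample(img: np.ndarray, cfg: DetectionConfig | None = None) -> DetectionResult:
    """Run the full recognition pipeline on one color frame.

    Stages: graying -> histogram -> maximum-entropy threshold -> binarize ->
    particle (area) filter -> excessive dilation -> particle analysis ->
    circle detection -> target selection.  A degenerate (single-bin)
    histogram raises; an empty field of view returns an unsuccessful result
    so the caller can move on to the next sample.
    """
    cfg = cfg or DetectionConfig()
    gray = vision.to_grayscale(img, rounding=cfg.rounding)
    hist = vision.compute_histogram(gray)
    scan = vision.max_entropy_threshold(hist)
    binary = vision.binarize(gray, scan.K, polarity=cfg.polarity)
    filtered = vision.particle_filter(binary, cfg.min_area, cfg.connectivity)
    dilated = vision.excessive_dilate(filtered, cfg.se_size, cfg.iterations)

    growth = vision.dilation_growth(cfg.se_size, cfg.iterations)
    radius_range = (cfg.radius_range[0] + growth, cfg.radius_range[1] + growth)

    particles = particle_analysis(dilated, cfg.connectivity)
    circles = detect_circles(dilated, radius_range, method=cfg.circle_method,
                             connectivity=cfg.connectivity,
                             circularity_threshold=cfg.circularity_threshold)
    result = select_target(particles, circles)
    if cfg.keep_stages:
        result.stage_images = {"gray": gray, "binary": binary,
                               "filtered": filtered, "dilated": dilated}
    return result


def detect_without_dilation(img: np.ndarray, cfg: DetectionConfig | None = None) -> DetectionResult:
    """Ablated pipeline with excessive dilation removed (for comparisons)."""
    cfg = replace(cfg or DetectionConfig(), iterations=0)
    return detect_sample(img, cfg)
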