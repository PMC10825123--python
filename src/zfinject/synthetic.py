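"""Seeded generators of ground-truthed synthetic brightfield scenes.

Emulates the inputs the recognition pipeline faces under the microscope: a
bright near-circular embryo (chorion outline), an elongated larva whose
yolk is the largest near-circular structure, foreground holes where the
transparent larval body drops below threshold, small debris blobs, and an
M x N agarose plate populated with both sample kinds.  Every scene carries
its geometric ground truth so detection accuracy can be scored exactly.

Photometry is deliberately simple — uniform background and foreground gray
levels plus additive Gaussian noise; see the methods note for what this
does and does not emulate about real acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .workflow import PlateLayout


class InvalidConfigError(ValueError):
    """Scene geometry does not fit the requested image."""


# default photometry: brightfield sample brighter than background.
# Both classes are given realistic intensity spread — an illumination ramp
# across the background and shading across the sample — because entropy-based
# thresholding assumes broad class distributions, as real frames provide;
# near-delta histograms would be segmented at the wrong place by any
# entropy-maximizing rule.
BACKGROUND_LEVEL = 60.0
BACKGROUND_RAMP = 20.0
FOREGROUND_LO = 155.0
FOREGROUND_HI = 210.0
FOREGROUND_LEVEL = 185.0  # flat level used for debris blobs


def _background(shape, rng) -> np.ndarray:
    """Uneven illumination: mean level plus a random linear ramp."""
    h, w = shape
    rr, cc = np.mgrid[:h, :w].astype(float)
    gx, gy = rng.uniform(-1.0, 1.0, 2)
    norm = max(1e-9, abs(gx) / 2 + abs(gy) / 2)
    ramp = (gx * (cc - w / 2) / w + gy * (rr - h / 2) / h) / norm
    return BACKGROUND_LEVEL + BACKGROUND_RAMP * ramp


def _shade_disc(base, center, radius, inner=FOREGROUND_LO, rim=FOREGROUND_HI):
    """Paint a disc with radial shading (darker center, brighter rim)."""
    rr, cc = np.ogrid[: base.shape[0], : base.shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    mask = dist <= radius
    base[mask] = inner + (rim - inner) * (dist[mask] / max(radius, 1e-9)) ** 2
    return mask


@dataclass
class SceneTruth:
    """Ground truth of one synthetic scene.

    ``center_true`` is the embryo center or the larval yolk center in
    (row, col) pixels; ``yolk_radius`` is the radius of that circular
    structure (the chorion radius for embryos).
    """

    kind: str
    center_true: tuple[float, float]
    yolk_radius: float
    body_outline: list[tuple[float, float]] | None
    impurities: list[tuple[tuple[float, float], int]]
    seed: int


def _finish(base: np.ndarray, noise_level: float, rng: np.random.Generator,
            dark_field: bool) -> np.ndarray:
    """Stack to RGB, add per-channel noise, quantize to uint8."""
    if dark_field:
        base = (BACKGROUND_LEVEL + FOREGROUND_LEVEL) - base
    rgb = np.repeat(base[:, :, None], 3, axis=2)
    if noise_level > 0:
        rgb = rgb + rng.normal(0.0, noise_level, size=rgb.shape)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _paint_disc(base, center, radius, level):
    rr, cc = np.ogrid[: base.shape[0], : base.shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    base[mask] = level
    return mask


def _place_impurities(rng, base, n, radius_range, keepout, shape):
    """Drop small bright debris discs away from the sample's keep-out zone.

    ``keepout(row, col, r)`` returns True where a blob of radius r may NOT go.
    """
    impurities = []
    h, w = shape
    attempts = 0
    while len(impurities) < n and attempts < 600 * max(1, n):
        attempts += 1
        r = float(rng.uniform(*radius_range))
        row = float(rng.uniform(r + 2, h - r - 2))
        col = float(rng.uniform(r + 2, w - r - 2))
        if keepout(row, col, r):
            continue
        mask = _paint_disc(base, (row, col), r, FOREGROUND_LEVEL)
        impurities.append(((row, col), int(mask.sum())))
    if len(impurities) < n:
        raise InvalidConfigError(f"could not place {n} impurities in a {h}x{w} scene")
    return impurities


def make_embryo_scene(seed: int, size: tuple[int, int] = (256, 256),
                      embryo_radius: float = 48.0, noise_level: float = 6.0,
                      n_impurities: int = 0,
                      impurity_radius: tuple[float, float] = (3.0, 8.0),
                      impurity_clearance: float = 96.0,
                      center_jitter: float = 10.0, ellipticity: float = 0.02,
                      dark_field: bool = False) -> tuple[np.ndarray, SceneTruth]:
    """Render one embryo frame: a bright near-circular chorion on a darker
    background, optional debris, seeded noise.

    The outline is a circle modulated by a random second-order harmonic of
    relative amplitude ``ellipticity``; being centrally symmetric, the
    perturbation leaves the true center well defined.  Returns the RGB
    image and its ground truth.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    margin = embryo_radius * (1 + ellipticity) + center_jitter + 4
    if 2 * margin >= min(h, w):
        raise InvalidConfigError(
            f"embryo radius {embryo_radius} does not fit a {h}x{w} image")

    center = (h / 2.0 + rng.uniform(-center_jitter, center_jitter),
              w / 2.0 + rng.uniform(-center_jitter, center_jitter))
    phase = rng.uniform(0, 2 * np.pi)

    base = _background((h, w), rng)
    rr, cc = np.ogrid[:h, :w]
    dist = np.hypot(rr - center[0], cc - center[1])
    theta = np.arctan2(rr - center[0], cc - center[1])
    r_theta = embryo_radius * (1.0 + ellipticity * np.cos(2 * theta + phase))
    mask = dist <= r_theta
    rel = (dist / np.maximum(r_theta, 1e-9))[mask]
    base[mask] = FOREGROUND_LO + (FOREGROUND_HI - FOREGROUND_LO) * rel**2

    def keepout(row, col, r):
        # debris must stay resolvable as a separate particle even after
        # excessive dilation, as in a Petri dish where it lies off-sample
        return (np.hypot(row - center[0], col - center[1])
                < embryo_radius * (1 + ellipticity) + r + impurity_clearance)

    impurities = _place_impurities(rng, base, n_impurities, impurity_radius, keepout, (h, w))
    for (_, area) in impurities:
        if area >= np.pi * embryo_radius**2:
            raise InvalidConfigError("impurity larger than the embryo")

    img = _finish(base, noise_level, rng, dark_field)
    truth = SceneTruth(kind="embryo", center_true=center, yolk_radius=embryo_radius,
                       body_outline=None, impurities=impurities, seed=seed)
    return img, truth


def make_larva_scene(seed: int, size: tuple[int, int] = (256, 352),
                     yolk_radius: float = 26.0, body_length: float = 170.0,
                     transparency_holes: int = 3, n_impurities: int = 0,
                     body_halfwidth: float = 10.0, head_radius: float = 13.0,
                     hole_radius: tuple[float, float] = (5.0, 9.0),
                     impurity_radius: tuple[float, float] = (3.0, 8.0),
                     impurity_clearance: float = 96.0,
                     noise_level: float = 6.0, max_angle_deg: float = 10.0,
                     dark_field: bool = False) -> tuple[np.ndarray, SceneTruth]:
    """Render one larva frame: an elongated body capsule with a head bulge
    and the yolk as its largest circular substructure.

    ``transparency_holes`` background-colored discs are punched into the
    foreground to emulate the transparent body regions lost at threshold;
    the first hole lands near the yolk center, so skipping hole-closing
    dilation visibly corrupts yolk localization.  The yolk is asserted to
    be strictly the largest near-circular structure in the scene.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    if not (yolk_radius > body_halfwidth and yolk_radius > head_radius):
        raise InvalidConfigError("yolk must be the widest structure of the larva")
    if impurity_radius[1] >= yolk_radius:
        raise InvalidConfigError("impurities must be smaller than the yolk")

    angle = math.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    direction = np.array([math.sin(angle), math.cos(angle)])  # (row, col)
    if rng.random() < 0.5:
        direction = -direction
    mid = np.array([h / 2.0 + rng.uniform(-8, 8), w / 2.0 + rng.uniform(-8, 8)])
    p0 = mid - direction * body_length / 2.0  # head end
    p1 = mid + direction * body_length / 2.0  # tail end
    yolk_center = p0 + direction * (0.28 * body_length)

    # geometric fit check, including the widest post-threshold extent
    reach = body_length / 2.0 + head_radius + 10
    for p in (p0, p1, yolk_center):
        if not (yolk_radius + 4 <= p[0] <= h - yolk_radius - 4
                and yolk_radius + 4 <= p[1] <= w - yolk_radius - 4):
            raise InvalidConfigError(f"larva geometry does not fit a {h}x{w} image")
    if 2 * reach >= max(h, w):
        raise InvalidConfigError(f"body length {body_length} does not fit a {h}x{w} image")

    base = _background((h, w), rng)
    rr, cc = np.mgrid[:h, :w].astype(float)
    # distance to the body axis segment -> capsule body, rim brighter
    d = p1 - p0
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / (d @ d)
    t = np.clip(t, 0.0, 1.0)
    seg_dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    body_mask = seg_dist <= body_halfwidth
    base[body_mask] = FOREGROUND_LO + (FOREGROUND_HI - FOREGROUND_LO) * (
        seg_dist[body_mask] / body_halfwidth) ** 2
    _shade_disc(base, p0, head_radius)
    _shade_disc(base, yolk_center, yolk_radius)

    # transparency holes: first one near the yolk center, rest along the body
    for i in range(transparency_holes):
        hr = float(rng.uniform(*hole_radius))
        if i == 0:
            off = rng.uniform(-3, 3, size=2)
            pos = yolk_center + off
        else:
            u = rng.uniform(0.45, 1.0)
            lateral = rng.uniform(-body_halfwidth * 0.5, body_halfwidth * 0.5)
            normal = np.array([-direction[1], direction[0]])
            pos = p0 + direction * (u * body_length) + normal * lateral
        _paint_disc(base, pos, hr, BACKGROUND_LEVEL)

    def keepout(row, col, r):
        tt = np.clip(((row - p0[0]) * d[0] + (col - p0[1]) * d[1]) / (d @ d), 0, 1)
        to_axis = math.hypot(row - (p0[0] + tt * d[0]), col - (p0[1] + tt * d[1]))
        to_yolk = math.hypot(row - yolk_center[0], col - yolk_center[1])
        to_head = math.hypot(row - p0[0], col - p0[1])
        c = impurity_clearance
        return (to_axis < body_halfwidth + r + c or to_yolk < yolk_radius + r + c
                or to_head < head_radius + r + c)

    impurities = _place_impurities(rng, base, n_impurities, impurity_radius, keepout, (h, w))

    outline = _capsule_outline(p0, p1, body_halfwidth, n=40)
    img = _finish(base, noise_level, rng, dark_field)
    truth = SceneTruth(kind="larva", center_true=(float(yolk_center[0]), float(yolk_center[1])),
                       yolk_radius=yolk_radius, body_outline=outline,
                       impurities=impurities, seed=seed)
    return img, truth


def _capsule_outline(p0, p1, halfwidth, n=40):
    """Polygon tracing the body capsule boundary."""
    d = p1 - p0
    axis_angle = math.atan2(d[0], d[1])
    pts = []
    for s in np.linspace(-np.pi / 2, np.pi / 2, n // 2):
        a = axis_angle + np.pi / 2 + s + np.pi / 2
        pts.append((p1[0] + halfwidth * math.sin(a), p1[1] + halfwidth * math.cos(a)))
    for s in np.linspace(np.pi / 2, 3 * np.pi / 2, n // 2):
        a = axis_angle + np.pi / 2 + s + np.pi / 2
        pts.append((p0[0] + halfwidth * math.sin(a), p0[1] + halfwidth * math.cos(a)))
    return [(float(r), float(c)) for r, c in pts]


@dataclass
class PlateCell:
    m: int
    n: int
    kind: str  # "embryo" | "larva" | "unrecognizable"
    image: np.ndarray
    truth: SceneTruth | None
    orientation: str = "forward"  # larva head-up vs head-down zone


@dataclass
class VirtualPlate:
    """One scene per groove of an M x N plate, keyed by 1-based (m, n)."""

    layout: PlateLayout
    cells: dict[tuple[int, int], PlateCell]
    seed: int
    failing_cells: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_embryos(self) -> int:
        return sum(c.kind == "embryo" for c in self.cells.values())

    @property
    def n_larvae(self) -> int:
        return sum(c.kind == "larva" for c in self.cells.values())


def embryo_column_count(n_cols: int) -> int:
    """Columns assigned to the embryo zone (left side of the plate): 6 of 11
    on the full prototype plate, scaled proportionally for narrower layouts."""
    return max(1, round(n_cols * 6 / 11)) if n_cols > 1 else 1


def make_plate(seed: int, layout: PlateLayout, failure_rate: float = 0.0,
               embryo_kwargs: dict | None = None,
               larva_kwargs: dict | None = None) -> VirtualPlate:
    """Populate a virtual plate: embryo zone on the left, larva zone on the
    right (split into forward / backward halves by head orientation).

    A seeded draw marks ``round(failure_rate * M * N)`` cells unrecognizable
    (featureless frames) to exercise the workflow's skip branch.  The full
    8 x 11 prototype layout yields 48 embryos and 40 larvae.
    """
    if not 0.0 <= failure_rate <= 1.0:
        raise InvalidConfigError("failure_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_embryo_cols = embryo_column_count(layout.N)
    n_fail = int(round(failure_rate * layout.n_cells))
    all_cells = [(m, n) for m in range(1, layout.M + 1) for n in range(1, layout.N + 1)]
    fail_idx = rng.choice(len(all_cells), size=n_fail, replace=False)
    failing = sorted(all_cells[i] for i in fail_idx)

    e_kw = dict(size=(224, 224), embryo_radius=36.0, center_jitter=6.0)
    e_kw.update(embryo_kwargs or {})
    l_kw = dict(size=(224, 320), yolk_radius=24.0, body_length=140.0,
                body_halfwidth=9.0, head_radius=12.0)
    l_kw.update(larva_kwargs or {})

    cells = {}
    for m, n in all_cells:
        cell_seed = int(rng.integers(0, 2**31 - 1))
        kind = "embryo" if n <= n_embryo_cols else "larva"
        orientation = "forward"
        if (m, n) in failing:
            shape = e_kw["size"] if kind == "embryo" else l_kw["size"]
            img = np.full(shape + (3,), int(BACKGROUND_LEVEL), dtype=np.uint8)
            cells[(m, n)] = PlateCell(m, n, "unrecognizable", img, None)
            continue
        if kind == "embryo":
            img, truth = make_embryo_scene(cell_seed, **e_kw)
        else:
            img, truth = make_larva_scene(cell_seed, **l_kw)
            if m > layout.M // 2:  # backward (head-down) zone
                orientation = "backward"
                img = img[::-1].copy()
                r, c = truth.center_true
                truth.center_true = (img.shape[0] - 1 - r, c)
                if truth.body_outline:
                    truth.body_outline = [(img.shape[0] - 1 - rr, cc)
                                          for rr, cc in truth.body_outline]
                truth.impurities = [((img.shape[0] - 1 - rr, cc), a)
                                    for (rr, cc), a in truth.impurities]
        cells[(m, n)] = PlateCell(m, n, kind, img, truth, orientation)
    return VirtualPlate(layout=layout, cells=cells, seed=seed, failing_cells=failing)
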