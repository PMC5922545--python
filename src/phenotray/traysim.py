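"""Seeded synthetic tray imagery with exact geometric ground truth.

The generator emulates an overhead phenotyping rig: a tray holding a 4 x 8
grid of pots photographed from above, with four red fiducial squares inset
on the tray, green rosettes growing on soil-colored background, moss-like
green specks, a lateral illumination (shadow) ramp, occasional neighbor
leaves intruding across pot boundaries, and a projective camera distortion.
Ground truth is defined geometrically (never by color): each pot carries an
exact binary rosette mask in pot-frame coordinates, and the true marker
centers and distortion matrix are recorded alongside the render.

Rosette areas follow a logistic growth curve, and each rendered mask is
pixel-adjusted so its foreground count equals the rounded logistic area —
the truth tables are exact, not approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor
from skimage.draw import ellipse as draw_ellipse


# Marker roles, shared with the geometry module.
ROLES = ("TL", "TR", "BL", "BR")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic rosette growth: area(t) = amax / (1 + (amax/a0 - 1) e^(-r t)).

    a0_px
        initial area at day 0, in pixels (0 means no plant ever emerges).
    amax_px
        asymptotic area in pixels.
    rate
        intrinsic growth rate per day.
    """

    a0_px: float = 50.0
    amax_px: float = 5000.0
    rate: float = 0.3


@dataclass(frozen=True)
class SimParams:
    """Scene description for one synthetic tray.

    Pixel dimensions must be positive, probabilities and strengths lie in
    [0, 1], and the distortion matrix must be invertible.  Identical
    ``SimParams`` plus an identical seed reproduce outputs bit-exactly.
    """

    n_rows: int = 4
    n_cols: int = 8
    pot_w_px: int = 224
    pot_h_px: int = 224
    marker_side_px: int = 19
    soil_rgb_mean: tuple[float, float, float] = (110.0, 80.0, 55.0)
    soil_rgb_std: tuple[float, float, float] = (8.0, 6.0, 5.0)
    plant_rgb_mean: tuple[float, float, float] = (60.0, 140.0, 50.0)
    plant_rgb_std: tuple[float, float, float] = (8.0, 10.0, 8.0)
    moss_rgb_mean: tuple[float, float, float] = (105.0, 125.0, 75.0)
    marker_rgb: tuple[float, float, float] = (205.0, 30.0, 35.0)
    moss_density: float = 0.003
    shadow_strength: float = 0.25
    intrusion_prob: float = 0.0
    distortion: np.ndarray | None = None  # 3x3, ideal canvas -> observed frame
    growth: GrowthParams = field(default_factory=GrowthParams)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_rows, self.n_cols, self.pot_w_px, self.pot_h_px,
               self.marker_side_px) <= 0:
            raise ValueError("pixel dimensions and grid counts must be > 0")
        for p in (self.moss_density, self.shadow_strength, self.intrusion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/strengths must lie in [0, 1]")
        if self.distortion is not None:
            h = np.asarray(self.distortion, dtype=float)
            if h.shape != (3, 3):
                raise ValueError("distortion must be a 3x3 matrix")
            if abs(np.linalg.det(h)) < 1e-12:
                raise ValueError("distortion matrix is not invertible")

    @property
    def canvas_shape(self) -> tuple[int, int]:
        """(height, width) of the ideal, undistorted tray canvas."""
        return (self.n_rows * self.pot_h_px, self.n_cols * self.pot_w_px)

    def ideal_marker_centers(self) -> dict[str, tuple[float, float]]:
        """Marker centers (x, y) on the ideal canvas, inset 2*P_W / 1*P_H."""
        pw, ph = self.pot_w_px, self.pot_h_px
        return {
            "TL": (2.0 * pw, 1.0 * ph),
            "TR": ((self.n_cols - 2.0) * pw, 1.0 * ph),
            "BL": (2.0 * pw, (self.n_rows - 1.0) * ph),
            "BR": ((self.n_cols - 2.0) * pw, (self.n_rows - 1.0) * ph),
        }


@dataclass
class SceneTruth:
    """Exact ground truth paired with one rendered tray frame."""

    pot_masks: list[np.ndarray]          # row-major, bool, (pot_h, pot_w)
    pot_areas: list[int]                 # foreground pixel count per pot
    marker_centers_ideal: dict[str, tuple[float, float]]
    marker_centers_observed: dict[str, tuple[float, float]]
    distortion: np.ndarray               # 3x3, ideal -> observed
    day: float


def logistic_area(g: GrowthParams, day: float) -> float:
    """Closed-form logistic area at time ``day`` (pixels)."""
    if g.a0_px <= 0.0:
        return 0.0
    return g.amax_px / (1.0 + (g.amax_px / g.a0_px - 1.0) * np.exp(-g.rate * day))


def random_distortion(rng: np.random.Generator, shape: tuple[int, int],
                      strength: float = 0.04) -> np.ndarray:
    """Random projective matrix perturbing the canvas corners inward.

    Corners move by up to ``strength`` of the canvas diagonal, always toward
    the interior, so all four markers stay in-frame for any strength < ~0.2.
    """
    from skimage.transform import ProjectiveTransform

    h, w = shape
    src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    amp = strength * np.hypot(h, w)
    inward = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
    dst = src + inward * rng.uniform(0.0, amp, size=(4, 2))
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf:  # pragma: no cover - src is a proper square
        raise RuntimeError("degenerate corner perturbation")
    return tf.params / tf.params[2, 2]


# ---------------------------------------------------------------------------
# rosette rendering


def _rosette_layout(rng: np.random.Generator) -> dict:
    """Per-pot leaf geometry: 4-12 ellipses radiating from the pot center."""
    n_leaves = int(rng.integers(4, 13))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_leaves))
    angles += rng.uniform(-0.15, 0.15, size=n_leaves)
    lengths = rng.uniform(0.6, 1.0, size=n_leaves)   # relative to scale
    widths = rng.uniform(0.30, 0.55, size=n_leaves)  # aspect of each leaf
    return {"angles": angles, "lengths": lengths, "widths": widths}


def _rasterize_rosette(layout: dict, scale: float,
                       shape: tuple[int, int]) -> np.ndarray:
    """Union of leaf ellipses at global size ``scale`` (pixels)."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = np.zeros(shape, dtype=bool)
    if scale <= 0:
        return mask
    for ang, ln, wd in zip(layout["angles"], layout["lengths"],
                           layout["widths"]):
        semi = ln * scale / 2.0  # semi-major axis
        if semi < 0.5:
            continue
        ecy = cy + semi * np.sin(ang)
        ecx = cx + semi * np.cos(ang)
        rr, cc = draw_ellipse(ecy, ecx, max(semi * wd, 0.6), semi,
                              shape=shape, rotation=-ang)
        mask[rr, cc] = True
    return mask


def _adjust_to_area(mask: np.ndarray, target: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Add/remove boundary pixels until popcount(mask) == target exactly."""
    mask = mask.copy()
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    for _ in range(64):
        n = int(mask.sum())
        if n == target:
            return mask
        if n > target:
            rim = mask & ~ndimage.binary_erosion(mask)
            ys, xs = np.nonzero(rim)
            if ys.size == 0:
                ys, xs = np.nonzero(mask)
            order = np.argsort(-d2[ys, xs], kind="stable")  # outermost first
            drop = order[: n - target]
            mask[ys[drop], xs[drop]] = False
        else:
            grow = ndimage.binary_dilation(mask) & ~mask
            ys, xs = np.nonzero(grow)
            if ys.size == 0:  # empty mask: seed at the center
                mask[int(round(cy)), int(round(cx))] = True
                continue
            order = np.argsort(d2[ys, xs], kind="stable")  # innermost first
            add = order[: target - n]
            mask[ys[add], xs[add]] = True
    return mask


def render_rosette_mask(layout: dict, target_area: int,
                        shape: tuple[int, int],
                        rng: np.random.Generator) -> np.ndarray:
    """Exact-area rosette mask: scale search, then boundary pixel adjustment."""
    target_area = int(round(target_area))
    mask = np.zeros(shape, dtype=bool)
    if target_area <= 0:
        return mask
    max_area = shape[0] * shape[1]
    target_area = min(target_area, max_area)
    # union area grows ~ scale^2; bracket then bisect
    lo, hi = 0.0, float(min(shape))
    for _ in range(40):
        mid = (lo + hi) / 2.0
        a = int(_rasterize_rosette(layout, mid, shape).sum())
        if a < target_area:
            lo = mid
        else:
            hi = mid
    mask = _rasterize_rosette(layout, hi, shape)
    return _adjust_to_area(mask, target_area, rng)


# ---------------------------------------------------------------------------
# tray composition


def _paint(rng: np.random.Generator, canvas: np.ndarray, where: np.ndarray,
           mean: tuple, std: tuple) -> None:
    n = int(where.sum())
    if n == 0:
        return
    cols = rng.normal(np.asarray(mean), np.asarray(std), size=(n, 3))
    canvas[where] = cols


def _moss_blobs(rng: np.random.Generator, shape: tuple[int, int],
                density: float) -> np.ndarray:
    """Small quasi-circular specks covering ~density of the canvas."""
    mask = np.zeros(shape, dtype=bool)
    if density <= 0:
        return mask
    mean_blob = np.pi * 2.0 ** 2
    n_blobs = max(1, int(density * shape[0] * shape[1] / mean_blob))
    ys = rng.integers(0, shape[0], size=n_blobs)
    xs = rng.integers(0, shape[1], size=n_blobs)
    radii = rng.uniform(1.0, 3.0, size=n_blobs)
    for y, x, r in zip(ys, xs, radii):
        rr, cc = draw_ellipse(y, x, r, r, shape=shape)
        mask[rr, cc] = True
    return mask


def _intrusion_mask(rng: np.random.Generator,
                    shape: tuple[int, int]) -> np.ndarray:
    """A neighbor leaf reaching in from a randomly chosen pot edge.

    Extends at most ~35% into the pot so it never touches a centered rosette
    of realistic size.
    """
    h, w = shape
    side = int(rng.integers(0, 4))
    length = rng.uniform(0.18, 0.32) * min(h, w)
    width = length * rng.uniform(0.35, 0.6)
    t = rng.uniform(0.2, 0.8)
    if side == 0:    # from left edge
        ecy, ecx, rot = t * h, 0.0, 0.0
    elif side == 1:  # from right edge
        ecy, ecx, rot = t * h, w - 1.0, 0.0
    elif side == 2:  # from top edge
        ecy, ecx, rot = 0.0, t * w, np.pi / 2
    else:            # from bottom edge
        ecy, ecx, rot = h - 1.0, t * w, np.pi / 2
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(ecy, ecx, width / 2.0, length, shape=shape,
                          rotation=rot)
    mask[rr, cc] = True
    return mask


def _render_ideal_canvas(params: SimParams, day: float,
                         rng: np.random.Generator,
                         layouts: list[dict]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Paint the undistorted tray canvas; return (float RGB canvas, pot masks)."""
    H, W = params.canvas_shape
    ph, pw = params.pot_h_px, params.pot_w_px
    canvas = np.empty((H, W, 3), dtype=float)
    _paint(rng, canvas, np.ones((H, W), dtype=bool),
           params.soil_rgb_mean, params.soil_rgb_std)

    target = logistic_area(params.growth, day)
    pot_masks: list[np.ndarray] = []
    plant_full = np.zeros((H, W), dtype=bool)
    for r in range(params.n_rows):
        for c in range(params.n_cols):
            layout = layouts[r * params.n_cols + c]
            mask = render_rosette_mask(layout, int(round(target)), (ph, pw), rng)
            pot_masks.append(mask)
            plant_full[r * ph:(r + 1) * ph, c * pw:(c + 1) * pw] |= mask
            if rng.uniform() < params.intrusion_prob:
                intr = _intrusion_mask(rng, (ph, pw))
                intr &= ~ndimage.binary_dilation(mask, iterations=3)
                sub = plant_full[r * ph:(r + 1) * ph, c * pw:(c + 1) * pw]
                sub |= intr  # plant-colored, but excluded from this pot's truth

    moss = _moss_blobs(rng, (H, W), params.moss_density) & ~plant_full
    _paint(rng, canvas, moss, params.moss_rgb_mean, params.soil_rgb_std)
    _paint(rng, canvas, plant_full, params.plant_rgb_mean, params.plant_rgb_std)

    # fiducial markers: filled red squares, painted last so nothing occludes
    half = params.marker_side_px // 2
    for x, y in params.ideal_marker_centers().values():
        # odd side: painted centroid coincides with the configured center
        y0, x0 = int(round(y)) - half, int(round(x)) - half
        s = params.marker_side_px
        _paint(rng, canvas,
               _rect_mask((H, W), y0, x0, s, s),
               params.marker_rgb, (4.0, 3.0, 3.0))

    # lateral illumination ramp (shadow from the gantry on one side)
    ramp = 1.0 - params.shadow_strength * (np.arange(W) / max(W - 1, 1))
    canvas *= ramp[None, :, None]
    return np.clip(canvas, 0, 255), pot_masks


def _rect_mask(shape, y0, x0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[max(y0, 0):y0 + h, max(x0, 0):x0 + w] = True
    return m


def generate_tray(params: SimParams, day: float = 0.0,
                  seed: int | None = None) -> tuple[np.ndarray, SceneTruth]:
    """Render one tray frame at growth time ``day``.

    Returns an (H, W, 3) uint8 RGB image and its :class:`SceneTruth`.  The
    per-pot leaf layout is derived from ``params.seed`` (stable across a
    time series); frame noise comes from ``seed`` (defaults to
    ``params.seed``).
    """
    from skimage.transform import ProjectiveTransform, warp

    frame_seed = params.seed if seed is None else seed
    layout_rng = np.random.default_rng(int(params.seed) & 0x7FFFFFFF)
    layouts = [_rosette_layout(layout_rng)
               for _ in range(params.n_rows * params.n_cols)]
    rng = np.random.default_rng(int(frame_seed) & 0x7FFFFFFF)

    canvas, pot_masks = _render_ideal_canvas(params, day, rng, layouts)
    ideal_centers = params.ideal_marker_centers()

    if params.distortion is None:
        hmat = np.eye(3)
        observed = canvas
    else:
        hmat = np.asarray(params.distortion, dtype=float)
        tf_inv = ProjectiveTransform(matrix=np.linalg.inv(hmat))
        observed = warp(canvas, tf_inv, output_shape=canvas.shape[:2],
                        preserve_range=True, cval=30.0)

    observed_centers = {
        role: tuple(_apply_h(hmat, np.array(pt)))
        for role, pt in ideal_centers.items()
    }
    truth = SceneTruth(
        pot_masks=pot_masks,
        pot_areas=[int(m.sum()) for m in pot_masks],
        marker_centers_ideal=ideal_centers,
        marker_centers_observed=observed_centers,
        distortion=hmat,
        day=day,
    )
    return observed.round().astype(np.uint8), truth


def _apply_h(h: np.ndarray, xy: np.ndarray) -> np.ndarray:
    v = h @ np.array([xy[0], xy[1], 1.0])
    return v[:2] / v[2]


def generate_timeseries(params: SimParams, schedule: list[float],
                        seed: int | None = None
                        ) -> list[tuple[np.ndarray, SceneTruth]]:
    """One frame per timestamp (days, strictly increasing)."""
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    days = np.asarray(schedule, dtype=float)
    if days.size > 1 and not np.all(np.diff(days) > 0):
        raise ValueError("schedule must be strictly increasing")
    base = params.seed if seed is None else seed
    out = []
    for i, day in enumerate(days):
        out.append(generate_tray(params, day=float(day),
                                 seed=(int(base) + 7919 * i) & 0x7FFFFFFF))
    return out


# ---------------------------------------------------------------------------
# ground-truth packs (pot-scale image/mask pairs for classifier training)


@dataclass(frozen=True)
class Variation:
    """Per-image appearance jitter for ground-truth packs.

    brightness
        multiplicative range applied to the whole image.
    shift_a, shift_b
        additive CIELAB a*/b* shift ranges (uniformly sampled per image);
        fixing lo == hi applies a constant color shift, which is how a
        distribution-shifted test split is built.
    """

    brightness: tuple[float, float] = (1.0, 1.0)
    shift_a: tuple[float, float] = (0.0, 0.0)
    shift_b: tuple[float, float] = (0.0, 0.0)


# Canonical "different acquisition environment" for shifted test splits:
# greener, wetter-looking background (a* pushed toward green) under dimmer
# illumination — the conditions that degrade a color-only classifier.
SHIFTED_TEST_VARIATION = Variation(brightness=(0.85, 0.85),
                                   shift_a=(-15.0, -15.0))


def generate_groundtruth_pack(params: SimParams, n_images: int,
                              variation: Variation | None = None,
                              seed: int | None = None,
                              day_range: tuple[float, float] | None = None,
                              ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pot-scale (image, mask) pairs sampled across growth stages.

    Growth stage is sampled uniformly over ``day_range`` (default: day 0 to
    the time the logistic reaches 95% of its asymptote), so packs cover all
    plant sizes.  Masks are exact.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    variation = variation or Variation()
    rng = np.random.default_rng((params.seed if seed is None else seed)
                                & 0x7FFFFFFF)
    g = params.growth
    if day_range is None:
        if g.a0_px > 0 and g.rate > 0 and g.amax_px > g.a0_px:
            t95 = np.log(19.0 * (g.amax_px / g.a0_px - 1.0)) / g.rate
        else:
            t95 = 30.0
        day_range = (0.0, float(t95))

    shape = (params.pot_h_px, params.pot_w_px)
    pairs = []
    for _ in range(n_images):
        day = rng.uniform(*day_range)
        layout = _rosette_layout(rng)
        target = int(round(logistic_area(g, day)))
        mask = render_rosette_mask(layout, target, shape, rng)

        img = np.empty(shape + (3,), dtype=float)
        _paint(rng, img, np.ones(shape, dtype=bool),
               params.soil_rgb_mean, params.soil_rgb_std)
        moss = _moss_blobs(rng, shape, params.moss_density) & ~mask
        _paint(rng, img, moss, params.moss_rgb_mean, params.soil_rgb_std)
        _paint(rng, img, mask, params.plant_rgb_mean, params.plant_rgb_std)
        ramp = 1.0 - params.shadow_strength * (np.arange(shape[1])
                                               / max(shape[1] - 1, 1))
        img *= ramp[None, :, None]

        img *= rng.uniform(*variation.brightness)
        da = rng.uniform(*variation.shift_a)
        db = rng.uniform(*variation.shift_b)
        img = np.clip(img, 0, 255)
        if da != 0.0 or db != 0.0:
            lab = skcolor.rgb2lab(img / 255.0)
            lab[..., 1] += da
            lab[..., 2] += db
            img = np.clip(skcolor.lab2rgb(lab), 0, 1) * 255.0
        pairs.append((img.round().astype(np.uint8), mask.astype(np.uint8)))
    return pairs


# ---------------------------------------------------------------------------
# dataset export


def write_dataset(frames: list[tuple[np.ndarray, SceneTruth]],
                  outdir: str | Path, params: SimParams) -> Path:
    """Write frames as PNGs plus a JSON manifest and a true-area CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["frame,pot_index,true_area_px"]
    for i, (img, truth) in enumerate(frames):
        Image.fromarray(img).save(outdir / f"tray_{i:04d}.png")
        for j, area in enumerate(truth.pot_areas):
            rows.append(f"{i},{j},{area}")
    (outdir / "true_areas.csv").write_text("\n".join(rows) + "\n")
    manifest = {
        "n_frames": len(frames),
        "seed": params.seed,
        "grid": [params.n_rows, params.n_cols],
        "pot_px": [params.pot_h_px, params.pot_w_px],
        "growth": {"a0_px": params.growth.a0_px,
                   "amax_px": params.growth.amax_px,
                   "rate": params.growth.rate},
        "days": [t.day for _, t in frames],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def write_pack(pairs: list[tuple[np.ndarray, np.ndarray]],
               outdir: str | Path) -> Path:
    """Write a ground-truth pack as image/mask PNG pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (img, mask) in enumerate(pairs):
        Image.fromarray(img).save(outdir / f"pot_{i:04d}.png")
        Image.fromarray((mask > 0).astype(np.uint8) * 255).save(
            outdir / f"pot_{i:04d}_mask.png")
    return outdir
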