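"""Fiducial-marker detection, perspective rectification, pot cropping.

Trays carry four red fiducial squares.  Rectification detects their
centers, estimates the homography mapping them onto fixed target
coordinates on an ideal canvas, warps the frame onto that canvas, and
slices the canvas into per-pot crops.

Coordinate conventions: 0-based, x rightward, y downward.  With pot size
``P_W x P_H`` on an ``n_rows x n_cols`` grid, the rectified canvas is
exactly ``(n_cols * P_W) x (n_rows * P_H)`` and the marker targets sit at
TL' = (2 P_W, P_H), TR' = (6 P_W, P_H), BL' = (2 P_W, 3 P_H),
BR' = (6 P_W, 3 P_H) for the default 4 x 8 grid — the markers span
4 P_W horizontally and 2 P_H vertically, inset from the tray corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import ProjectiveTransform, warp

ROLES = ("TL", "TR", "BL", "BR")


@dataclass(frozen=True)
class TrayGeometry:
    """Pot-grid geometry of a tray on the rectified canvas."""

    pot_w: int = 224
    pot_h: int = 224
    n_rows: int = 4
    n_cols: int = 8

    def __post_init__(self):
        if min(self.pot_w, self.pot_h, self.n_rows, self.n_cols) <= 0:
            raise ValueError("geometry fields must be positive")

    @property
    def canvas_shape(self) -> tuple[int, int]:
        """(height, width) of the rectified canvas."""
        return (self.n_rows * self.pot_h, self.n_cols * self.pot_w)


@dataclass
class MarkerSet:
    """Four fiducial centers keyed by corner role, with provenance.

    ``centers[role] = (x, y)``; ``provenance[role]`` is ``"detected"`` or
    ``"recovered"``.  A partial set (during detection/recovery) may hold
    fewer than four roles.
    """

    centers: dict[str, tuple[float, float]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for role in self.centers:
            if role not in ROLES:
                raise ValueError(f"unknown corner role {role!r}")
            self.provenance.setdefault(role, "detected")

    @property
    def complete(self) -> bool:
        return all(r in self.centers for r in ROLES)

    def missing(self) -> list[str]:
        return [r for r in ROLES if r not in self.centers]

    def as_array(self) -> np.ndarray:
        """(4, 2) array of (x, y) in TL, TR, BL, BR order."""
        if not self.complete:
            raise ValueError(f"marker set missing roles: {self.missing()}")
        return np.array([self.centers[r] for r in ROLES], dtype=float)


@dataclass(frozen=True)
class MarkerConfig:
    """Red-marker color threshold (HSV) and contour filtering parameters.

    Red hue wraps around 0, so a pixel is a candidate when its hue is below
    ``hue_low`` or above ``hue_high`` with saturation/value above the
    minimums.  Candidate contours under ``area_threshold`` pixels are
    discarded; surviving contours closer than ``merge_dist`` are merged
    while more than four remain.
    """

    hue_low: float = 0.05
    hue_high: float = 0.95
    sat_min: float = 0.45
    val_min: float = 0.25
    area_threshold: int = 150
    merge_dist: float = 5.0


class MarkerDetectionError(RuntimeError):
    """Fewer than four markers found; carries the partial set."""

    def __init__(self, partial: MarkerSet, n_candidates: int):
        self.partial = partial
        self.n_candidates = n_candidates
        super().__init__(
            f"found {n_candidates} marker candidate(s), need 4; "
            f"missing roles: {partial.missing()}")


def _red_mask(image: np.ndarray, config: MarkerConfig) -> np.ndarray:
    hsv = skcolor.rgb2hsv(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return (((h < config.hue_low) | (h > config.hue_high))
            & (s >= config.sat_min) & (v >= config.val_min))


def _grayscale_refine(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Re-classify candidate pixels by a binary (Otsu) grayscale threshold.

    Skipped when the masked region is nearly uniform in grayscale — a clean
    marker needs no refinement and Otsu would split its own pixels.
    """
    vals = skcolor.rgb2gray(image)[mask]
    if vals.size < 2 or vals.std() < 0.08:
        return mask
    thr = threshold_otsu(vals)
    gray = skcolor.rgb2gray(image)
    bright = mask & (gray >= thr)
    dark = mask & (gray < thr)
    return bright if bright.sum() >= dark.sum() else dark


def assign_roles(centers: list[tuple[float, float]],
                 provenance: str = "detected") -> MarkerSet:
    """Assign TL/TR/BL/BR roles: split top/bottom by y, then left/right by x.

    Works for 2-4 centers by quadrant relative to the candidate centroid
    when a full y/x split is ambiguous; for the standard four-center case
    this reduces to sort-by-y then sort-by-x within pairs.
    """
    pts = np.asarray(centers, dtype=float)
    out: dict[str, tuple[float, float]] = {}
    if len(pts) == 4:
        order = np.argsort(pts[:, 1], kind="stable")
        top, bottom = pts[order[:2]], pts[order[2:]]
        top = top[np.argsort(top[:, 0], kind="stable")]
        bottom = bottom[np.argsort(bottom[:, 0], kind="stable")]
        out = {"TL": tuple(top[0]), "TR": tuple(top[1]),
               "BL": tuple(bottom[0]), "BR": tuple(bottom[1])}
    else:
        cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
        for x, y in pts:
            role = ("T" if y <= cy else "B") + ("L" if x <= cx else "R")
            if role in out:
                raise ValueError("ambiguous corner-role assignment")
            out[role] = (float(x), float(y))
    return MarkerSet(centers=out,
                     provenance={r: provenance for r in out})


def _merge_adjacent(props: list, merge_dist: float) -> list:
    """Merge candidate contours whose bounding boxes are within merge_dist.

    Iterates while more than four candidates remain and a mergeable pair
    exists.  Merging replaces a pair with their area-weighted union stats.
    """
    cands = [{"area": p.area,
              "centroid": np.array([p.centroid[1], p.centroid[0]]),  # (x, y)
              "bbox": np.array(p.bbox, dtype=float)}  # (minr, minc, maxr, maxc)
             for p in props]

    def bbox_gap(a, b) -> float:
        dy = max(a[0] - b[2], b[0] - a[2], 0.0)
        dx = max(a[1] - b[3], b[1] - a[3], 0.0)
        return float(np.hypot(dy, dx))

    while len(cands) > 4:
        best = None
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                gap = bbox_gap(cands[i]["bbox"], cands[j]["bbox"])
                if gap <= merge_dist and (best is None or gap < best[0]):
                    best = (gap, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = cands[i], cands[j]
        w = a["area"] + b["area"]
        merged = {
            "area": w,
            "centroid": (a["centroid"] * a["area"]
                         + b["centroid"] * b["area"]) / w,
            "bbox": np.array([min(a["bbox"][0], b["bbox"][0]),
                              min(a["bbox"][1], b["bbox"][1]),
                              max(a["bbox"][2], b["bbox"][2]),
                              max(a["bbox"][3], b["bbox"][3])]),
        }
        cands = [c for k, c in enumerate(cands) if k not in (i, j)]
        cands.append(merged)
    return cands


def detect_markers(image: np.ndarray,
                   config: MarkerConfig | None = None) -> MarkerSet:
    """Locate the four red fiducial centers in a tray frame.

    Pipeline: HSV red threshold -> grayscale binary re-classification ->
    connected contours -> drop areas below ``config.area_threshold`` ->
    merge adjacent contours while more than four remain (keep the four
    largest if still over) -> centroid per marker -> corner-role
    assignment.

    Raises :class:`MarkerDetectionError` (carrying the partial set) when
    fewer than four candidates survive.
    """
    config = config or MarkerConfig()
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    mask = _red_mask(image, config)
    if mask.any():
        mask = _grayscale_refine(image, mask)
    labeled = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labeled)
             if p.area >= config.area_threshold]
    cands = _merge_adjacent(props, config.merge_dist)
    if len(cands) > 4:
        cands = sorted(cands, key=lambda c: -c["area"])[:4]
    centers = [tuple(c["centroid"]) for c in cands]
    if len(centers) < 4:
        partial = (assign_roles(centers) if len(centers) >= 2
                   else MarkerSet(centers=(
                       {"TL": centers[0]} if centers else {})))
        raise MarkerDetectionError(partial, len(centers))
    return assign_roles(centers)


def recover_missing_markers(partial: MarkerSet,
                            prev: MarkerSet | None = None,
                            next: MarkerSet | None = None) -> MarkerSet:
    """Fill missing corner roles from a temporal neighbor's same-role center.

    The previous visit wins when both neighbors carry the role.  Raises if
    a role is missing from the partial set and every supplied neighbor.
    """
    if partial.complete:
        return MarkerSet(centers=dict(partial.centers),
                         provenance=dict(partial.provenance))
    if prev is None and next is None:
        raise ValueError("markers missing and no temporal neighbor supplied")
    centers = dict(partial.centers)
    provenance = dict(partial.provenance)
    for role in partial.missing():
        source = None
        for neighbor in (prev, next):
            if neighbor is not None and role in neighbor.centers:
                source = neighbor
                break
        if source is None:
            raise ValueError(f"role {role} missing from partial set and "
                             f"all temporal neighbors")
        centers[role] = source.centers[role]
        provenance[role] = "recovered"
    return MarkerSet(centers=centers, provenance=provenance)


def target_points(geom: TrayGeometry) -> MarkerSet:
    """Marker target coordinates on the rectified canvas.

    TL' = (2 P_W, P_H); the targets span ``(n_cols - 4) P_W`` horizontally
    and ``(n_rows - 2) P_H`` vertically (4 P_W x 2 P_H on the standard
    4 x 8 grid).
    """
    pw, ph = geom.pot_w, geom.pot_h
    centers = {
        "TL": (2.0 * pw, 1.0 * ph),
        "TR": ((geom.n_cols - 2.0) * pw, 1.0 * ph),
        "BL": (2.0 * pw, (geom.n_rows - 1.0) * ph),
        "BR": ((geom.n_cols - 2.0) * pw, (geom.n_rows - 1.0) * ph),
    }
    return MarkerSet(centers=centers,
                     provenance={r: "target" for r in centers})


def estimate_homography(src: MarkerSet, dst: MarkerSet) -> np.ndarray:
    """Homography mapping source marker centers onto target centers.

    Returns a 3x3 matrix normalized so the bottom-right entry is 1.
    Raises on degenerate (e.g. collinear) source points.
    """
    s = src.as_array()
    d = dst.as_array()
    tf = ProjectiveTransform.from_estimate(s, d)
    if not tf or not np.all(np.isfinite(tf.params)):
        raise ValueError("homography estimation failed (degenerate points)")
    h = tf.params
    if abs(h[2, 2]) < 1e-12 or abs(np.linalg.det(h)) < 1e-12:
        raise ValueError("homography estimation failed (singular matrix)")
    return h / h[2, 2]


def apply_homography(h: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homography to (N, 2) points in (x, y) order."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ones = np.ones((pts.shape[0], 1))
    v = (h @ np.hstack([pts, ones]).T).T
    return v[:, :2] / v[:, 2:3]


def warp_tray(image: np.ndarray, h: np.ndarray,
              geom: TrayGeometry) -> np.ndarray:
    """Perspective-warp a frame onto the rectified tray canvas.

    ``h`` maps observed coordinates onto canvas coordinates; the output is
    exactly ``(n_rows * P_H, n_cols * P_W)`` pixels.
    """
    tf_out_to_in = ProjectiveTransform(matrix=np.linalg.inv(h))
    out = warp(image.astype(float), tf_out_to_in,
               output_shape=geom.canvas_shape, preserve_range=True, cval=0.0)
    if image.dtype == np.uint8:
        return np.clip(out, 0, 255).round().astype(np.uint8)
    return out


def crop_pots(corrected: np.ndarray, geom: TrayGeometry) -> list[np.ndarray]:
    """Slice the rectified canvas into row-major per-pot crops.

    Pot (r, c) occupies the half-open window
    [c*P_W, (c+1)*P_W) x [r*P_H, (r+1)*P_H); the windows tile the canvas
    exactly, so the canvas shape must match the geometry.
    """
    expected = geom.canvas_shape
    if corrected.shape[:2] != expected:
        raise ValueError(f"canvas shape {corrected.shape[:2]} does not match "
                         f"geometry {expected}")
    crops = []
    for r in range(geom.n_rows):
        for c in range(geom.n_cols):
            crops.append(corrected[r * geom.pot_h:(r + 1) * geom.pot_h,
                                   c * geom.pot_w:(c + 1) * geom.pot_w])
    return crops


def rectify(image: np.ndarray, geom: TrayGeometry,
            config: MarkerConfig | None = None,
            prev: MarkerSet | None = None,
            next: MarkerSet | None = None
            ) -> tuple[np.ndarray, MarkerSet, np.ndarray]:
    """Detect (recovering from neighbors if needed), estimate, and warp.

    Returns (corrected canvas, marker set used, homography).
    """
    try:
        markers = detect_markers(image, config)
    except MarkerDetectionError as err:
        if prev is None and next is None:
            raise
        markers = recover_missing_markers(err.partial, prev=prev, next=next)
    h = estimate_homography(markers, target_points(geom))
    return warp_tray(image, h, geom), markers, h
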