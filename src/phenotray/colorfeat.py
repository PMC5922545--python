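"""CIELAB conversion, SLIC over-segmentation, per-superpixel color features.

Color is the discriminative cue for separating rosettes from soil, so pot
images are converted to CIE L*a*b* (sRGB primaries, D65 white point) and
over-segmented with SLIC in that space.  Each superpixel contributes one
feature row — its mean (L*, a*, b*) — giving an N x 3 matrix where N, the
number of superpixels, varies by image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage.segmentation import slic


@dataclass
class SuperpixelMap:
    """Pixel -> superpixel assignment plus optional mean-Lab features.

    ``labels`` has the source image's height/width with integer ids forming
    the contiguous range 0..n-1; ``features`` (when attached) is an (n, 3)
    float matrix of per-superpixel mean (L*, a*, b*).
    """

    labels: np.ndarray
    n: int
    features: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0:
            raise ValueError("superpixel ids must be non-negative")
        if self.n != int(self.labels.max(initial=-1)) + 1:
            raise ValueError("n must equal max label + 1 (contiguous ids)")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape != (self.n, 3):
                raise ValueError("features must be an (n, 3) matrix")

    def pixel_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n)


def to_lab(image: np.ndarray) -> np.ndarray:
    """8-bit RGB -> float CIE L*a*b* (L in [0, 100], a*/b* signed)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB input")
    return skcolor.rgb2lab(image / 255.0)


def superpixels(lab: np.ndarray, n_target: int = 700,
                compactness: float = 0.5) -> SuperpixelMap:
    """SLIC over-segmentation of a Lab image into ~n_target superpixels.

    The realized count N may differ from ``n_target`` (SLIC enforces
    connectivity and merges orphan fragments).  Labels are relabeled to the
    contiguous range 0..N-1.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target > lab.shape[0] * lab.shape[1]:
        raise ValueError("n_target exceeds the pixel count")
    labels = slic(lab, n_segments=n_target, compactness=compactness,
                  convert2lab=False, enforce_connectivity=True,
                  start_label=0, channel_axis=-1)
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(lab.shape[:2])
    return SuperpixelMap(labels=labels, n=int(labels.max()) + 1)


def mean_features(lab: np.ndarray, sp: SuperpixelMap) -> np.ndarray:
    """Per-superpixel mean (L*, a*, b*): the (N, 3) feature matrix.

    Row i is the arithmetic mean of the Lab values over pixels with id i.
    """
    if sp.labels.shape != lab.shape[:2]:
        raise ValueError("label image shape does not match the Lab image")
    flat = sp.labels.ravel()
    counts = np.bincount(flat, minlength=sp.n).astype(float)
    if np.any(counts == 0):
        raise RuntimeError("empty superpixel id encountered")
    feats = np.empty((sp.n, 3), dtype=float)
    for ch in range(3):
        feats[:, ch] = np.bincount(flat, weights=lab[..., ch].ravel(),
                                   minlength=sp.n) / counts
    return feats


def extract(image: np.ndarray, n_target: int = 700,
            compactness: float = 0.5) -> SuperpixelMap:
    """Convenience: RGB pot image -> SuperpixelMap with features attached."""
    lab = to_lab(image)
    sp = superpixels(lab, n_target=n_target, compactness=compactness)
    sp.features = mean_features(lab, sp)
    return sp
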