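"""Apply a trained classifier to pot images and post-process the mask.

The raw mask is a union of whole superpixels (classifier output broadcast
back to pixels).  Post-processing then (1) erodes to remove small
misclassified specks and (2) keeps only the connected component at the pot
center — a top-view pot holds one centered rosette, so material touching in
from neighbors or isolated moss patches is discarded regardless of size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from phenotray.colorfeat import SuperpixelMap, extract
from phenotray.training import SuperpixelClassifier


@dataclass
class SegMask:
    """Binary segmentation mask with its pipeline stage tag."""

    data: np.ndarray            # bool, pot-image shape
    stage: str                  # raw | eroded | center-retained

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)

    @property
    def area(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class PipelineParams:
    """Segmentation pipeline knobs (defaults as deployed)."""

    n_superpixels: int = 700
    compactness: float = 0.5
    erode_radius: int = 1        # square structuring element (2r+1)^2
    erode_iterations: int = 1
    connectivity: int = 2        # 2 = 8-neighbor components


def classify(features: np.ndarray, model: SuperpixelClassifier
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-superpixel labels and continuous scores: one of each per row."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 3:
        raise ValueError("features must be an (N, 3) matrix")
    return model.predict(features), model.predict_scores(features)


def mask_from_labels(sp: SuperpixelMap, labels: np.ndarray) -> SegMask:
    """Broadcast superpixel labels back to pixels (the raw mask)."""
    labels = np.asarray(labels).ravel()
    if len(labels) != sp.n:
        raise ValueError(f"got {len(labels)} labels for {sp.n} superpixels")
    return SegMask(data=labels.astype(bool)[sp.labels], stage="raw")


def erode(mask: SegMask, radius: int = 1, iterations: int = 1) -> SegMask:
    """Morphological erosion with a (2r+1) square structuring element."""
    if iterations < 0 or radius < 0:
        raise ValueError("radius and iterations must be >= 0")
    out = mask.data
    if iterations > 0 and radius > 0 and out.any():
        selem = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
        out = ndimage.binary_erosion(out, structure=selem,
                                     iterations=iterations)
    return SegMask(data=out, stage="eroded")


def retain_center(mask: SegMask, connectivity: int = 2) -> SegMask:
    """Keep only the connected component at (or nearest) the image center.

    If the center pixel is foreground its component is kept; otherwise the
    component whose centroid lies nearest the center wins.  Size is
    deliberately not the criterion — a large intruding neighbor leaf must
    lose to a small centered rosette.  An empty mask stays empty.
    """
    if not mask.data.any():
        return SegMask(data=mask.data.copy(), stage="center-retained")
    structure = ndimage.generate_binary_structure(2, connectivity)
    labeled, n = ndimage.label(mask.data, structure=structure)
    cy, cx = (mask.data.shape[0] - 1) / 2.0, (mask.data.shape[1] - 1) / 2.0
    center_label = labeled[int(round(cy)), int(round(cx))]
    if center_label == 0:
        centroids = ndimage.center_of_mass(mask.data, labeled,
                                           range(1, n + 1))
        d = [(yc - cy) ** 2 + (xc - cx) ** 2 for yc, xc in centroids]
        center_label = 1 + int(np.argmin(d))
    return SegMask(data=labeled == center_label, stage="center-retained")


@dataclass
class SegResult:
    """Output of the full per-pot segmentation pipeline."""

    raw: SegMask
    eroded: SegMask
    final: SegMask
    area: int
    scores: np.ndarray


def segment_pot(image: np.ndarray, model: SuperpixelClassifier,
                params: PipelineParams | None = None) -> SegResult:
    """Full pipeline: Lab -> SLIC -> features -> classify -> mask ->
    erode -> retain center.  Returns all stages plus the final pixel area.
    """
    params = params or PipelineParams()
    stage = "feature extraction"
    try:
        sp = extract(image, n_target=params.n_superpixels,
                     compactness=params.compactness)
        stage = "classification"
        labels, scores = classify(sp.features, model)
        stage = "mask reconstruction"
        raw = mask_from_labels(sp, labels)
        stage = "erosion"
        eroded = erode(raw, radius=params.erode_radius,
                       iterations=params.erode_iterations)
        stage = "center retention"
        final = retain_center(eroded, connectivity=params.connectivity)
    except Exception as err:
        raise RuntimeError(f"segmentation failed at stage "
                           f"'{stage}': {err}") from err
    return SegResult(raw=raw, eroded=eroded, final=final,
                     area=final.area, scores=scores)


def iou(mask: np.ndarray, truth: np.ndarray) -> float:
    """Pixel-level intersection over union; 1.0 when both masks are empty."""
    a = np.asarray(mask).astype(bool)
    b = np.asarray(truth).astype(bool)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)
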