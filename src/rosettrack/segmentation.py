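"""Rosette detection: thresholding, watershed labeling, noise pruning, measurement.

A filtered frame and a background threshold yield a foreground mask.  Touching
rosette leaves are split with a watershed on the negated Euclidean distance
map; small or thin objects (soil speckles, pot-edge slivers) are pruned by
size/perimeter/compactness rules that depend on how big the plant was the
previous day; the survivors are merged into a single rosette, from which area,
centroid and the maximum centroid-to-edge radius are measured.

The watershed exposes two knobs borrowed from the original tooling:
``tolerance`` (minimum depth of a distance-map peak for it to seed a separate
object, implemented as the h-maxima depth) and ``extension`` (radius within
which neighbouring seeds are merged).  For objects separated by background
gaps wider than ``extension`` the result coincides with plain connected
components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.segmentation import watershed

__all__ = [
    "SegmentationParams",
    "CandidateObject",
    "DetectionResult",
    "binarize",
    "label_objects",
    "prune_noise",
    "merge_and_measure",
    "mask_radius",
]

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity
_SQUARE = ndi.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass(frozen=True)
class SegmentationParams:
    watershed_tolerance: float = 1.0
    watershed_extension: int = 3
    n_small: int = 30
    n_large: int = 60
    area_switch: float = 20_000.0
    ratio_min: float = 1.5
    radius_padding: float = 0.5

    def __post_init__(self) -> None:
        if min(self.watershed_tolerance, self.watershed_extension, self.n_small,
               self.n_large, self.area_switch, self.ratio_min) <= 0:
            raise ValueError("segmentation parameters must be positive")
        if self.n_small > self.n_large:
            raise ValueError("n_small must not exceed n_large")


@dataclass
class CandidateObject:
    """One labeled foreground object with its hull-style features."""

    label: int
    surface_area: int
    perimeter: int
    centroid: tuple[float, float]  # (x, y) = (col, row)
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)

    def __post_init__(self) -> None:
        if self.surface_area < 1:
            raise ValueError("surface_area must be >= 1")
        if self.perimeter <= 0:
            raise ValueError("perimeter must be positive")


@dataclass
class DetectionResult:
    mask: np.ndarray
    area: int
    radius: float
    centroid: tuple[float, float] | None
    kept: list[CandidateObject]
    removed: list[CandidateObject]
    threshold: float | None = None


def binarize(F: np.ndarray, T: float) -> np.ndarray:
    """Foreground mask: pixels with filtered intensity >= T.

    The model's convention sets pixels below the threshold to background; the
    boundary (== T) is kept as foreground.
    """
    return np.asarray(F) >= T


def _boundary_count(obj_mask: np.ndarray) -> int:
    """Perimeter as boundary-pixel count: object pixels with a 4-neighbour
    outside the object (image border counts as outside)."""
    interior = ndi.binary_erosion(obj_mask, structure=_CROSS, border_value=0)
    return int((obj_mask & ~interior).sum())


def label_objects(foreground: np.ndarray, params: SegmentationParams = SegmentationParams()) -> list[CandidateObject]:
    """Index foreground objects by watershed on the negated distance map.

    Seeds are regional maxima of the Euclidean distance map deeper than
    ``watershed_tolerance`` (h-maxima); seeds within ``watershed_extension``
    of each other are merged before flooding.  Objects are 8-connected.
    """
    fg = np.asarray(foreground).astype(bool)
    if not fg.any():
        return []
    dist = ndi.distance_transform_edt(fg)
    peaks = morphology.h_maxima(dist, params.watershed_tolerance)
    if not peaks.any():  # e.g. a 1-px-thin foreground; fall back to plain labels
        labels, _ = ndi.label(fg, structure=_SQUARE)
    else:
        merged = morphology.dilation(peaks, morphology.disk(params.watershed_extension))
        markers, _ = ndi.label(merged, structure=_SQUARE)
        labels = watershed(-dist, markers=markers, mask=fg, connectivity=2)
        if (fg & (labels == 0)).any():  # pixels unreachable from any seed
            extra, n_extra = ndi.label(fg & (labels == 0), structure=_SQUARE)
            labels = labels + np.where(extra > 0, extra + labels.max(), 0)

    objects: list[CandidateObject] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        obj = labels == lab
        rr, cc = np.nonzero(obj)
        objects.append(
            CandidateObject(
                label=int(lab),
                surface_area=int(rr.size),
                perimeter=_boundary_count(obj),
                centroid=(float(cc.mean()), float(rr.mean())),
                pixels=(rr, cc),
            )
        )
    return objects


def prune_noise(
    objects: list[CandidateObject],
    prev_area: float,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[CandidateObject], list[CandidateObject]]:
    """Remove noise objects by the size/perimeter/ratio rule.

    With N = ``n_small`` if the previous-day area is at most ``area_switch``
    (else ``n_large``), an object is noise iff surface area < N, or
    perimeter < N, or surface area / perimeter < ``ratio_min``.
    """
    if prev_area < 0:
        raise ValueError("prev_area must be nonnegative")
    n = params.n_small if prev_area <= params.area_switch else params.n_large
    kept, removed = [], []
    for obj in objects:
        noisy = (
            obj.surface_area < n
            or obj.perimeter < n
            or obj.surface_area / obj.perimeter < params.ratio_min
        )
        (removed if noisy else kept).append(obj)
    return kept, removed


def mask_radius(mask: np.ndarray, padding: float = 0.5) -> tuple[float, tuple[float, float] | None]:
    """Maximum centroid-to-edge distance of a binary mask, plus centroid.

    The radius is measured from the unweighted pixel centroid to the centers
    of boundary pixels, padded by half a pixel so that a rasterized disk's
    circular area covers its own pixel count.  Returns (radius, (x, y));
    an empty mask gives (0.0, None).
    """
    mask = np.asarray(mask).astype(bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return 0.0, None
    cr, ccen = rr.mean(), cc.mean()
    boundary = mask & ~ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    br, bc = np.nonzero(boundary)
    radius = float(np.sqrt((br - cr) ** 2 + (bc - ccen) ** 2).max()) + padding
    return radius, (float(ccen), float(cr))


def merge_and_measure(
    kept: list[CandidateObject],
    shape: tuple[int, int],
    params: SegmentationParams = SegmentationParams(),
    threshold: float | None = None,
    removed: list[CandidateObject] | None = None,
) -> DetectionResult:
    """Combine kept objects into one rosette and measure area and radius."""
    mask = np.zeros(shape, dtype=bool)
    for obj in kept:
        mask[obj.pixels] = True
    area = int(mask.sum())
    if area == 0:
        return DetectionResult(mask=mask, area=0, radius=0.0, centroid=None,
                               kept=list(kept), removed=list(removed or []),
                               threshold=threshold)
    radius, centroid = mask_radius(mask, params.radius_padding)
    return DetectionResult(mask=mask, area=area, radius=radius, centroid=centroid,
                           kept=list(kept), removed=list(removed or []),
                           threshold=threshold)
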