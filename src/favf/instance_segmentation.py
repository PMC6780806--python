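"""Watershed-based separation of overlapped fluorescent cells.

Cells in suspension stick together through electrostatic and adhesive
forces; template matching then returns intersecting bounding boxes, which
triggers this module.  The chain is classical: keep the colour channel of
interest, binarise with Otsu's threshold, clean with a morphological
opening, seed one marker per distance-transform peak (plus a background
"water hole" in the top-left corner), and run marker-controlled watershed on
the inverted smoothed intensity so that bright cell centres act as basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

from .errors import InvalidParameterError
from .planar_locating import Detection

__all__ = [
    "MarkerImage",
    "SegmentationResult",
    "overlap_judgement",
    "channel_threshold",
    "binarize",
    "morphology_clean",
    "distance_markers",
    "watershed_separate",
    "segment_overlapped",
]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}

_BACKGROUND_LABEL = 1
_BLOCK = 5  # side of the corner background-marker block, px


@dataclass
class MarkerImage:
    """Integer seed grid: 0 unassigned, 1 background, >=2 cell markers."""

    labels: np.ndarray

    @property
    def cell_marker_count(self) -> int:
        return int(max(0, self.labels.max() - _BACKGROUND_LABEL))


@dataclass
class SegmentationResult:
    labels: np.ndarray
    centers: list[tuple[float, float]]  # (x, y) px per cell label
    count: int
    under_segmented: bool = False


def _boxes_intersect(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    iw = min(ax + aw, bx + bw) - max(ax, bx)
    ih = min(ay + ah, by + bh) - max(ay, by)
    return iw > 0 and ih > 0


def overlap_judgement(detections: list[Detection]) -> list[list[int]]:
    """Group detections whose bounding boxes intersect (transitive closure).

    Singleton groups bypass segmentation; larger groups trigger it.
    """
    n = len(detections)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _boxes_intersect(detections[i].bbox, detections[j].bbox):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for g in sorted(groups.values(), key=lambda g: g[0])]


def channel_threshold(image: np.ndarray, channel: str, threshold: float) -> np.ndarray:
    """Retain one colour channel where it exceeds ``threshold``, else 0."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError("channel_threshold expects an RGB image")
    if channel not in _CHANNEL_INDEX:
        raise InvalidParameterError(f"unknown channel {channel!r}")
    ch = img[..., _CHANNEL_INDEX[channel]]
    return np.where(ch > threshold, ch, 0.0)


def binarize(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Otsu global threshold.  Returns (binary, degenerate_flag); a constant
    image yields an all-background mask with the flag set."""
    arr = np.asarray(mask, dtype=float)
    if arr.ndim != 2:
        raise InvalidParameterError("binarize expects a single-channel image")
    if np.ptp(arr) == 0:
        return np.zeros(arr.shape, dtype=bool), True
    t = threshold_otsu(arr)
    return arr > t, False


def morphology_clean(binary: np.ndarray, radius: int = 2) -> np.ndarray:
    """Opening with a disc element: removes speckle, severs thin bridges."""
    if radius < 1:
        raise InvalidParameterError("radius must be >= 1")
    return opening(np.asarray(binary, dtype=bool), disk(radius))


def _corner_block(shape: tuple[int, int], intensity: np.ndarray | None) -> tuple[slice, slice]:
    """Top-left 5x5 block, falling back to the darkest free corner when the
    foreground touches the origin."""
    corners = {
        "tl": (slice(0, _BLOCK), slice(0, _BLOCK)),
        "tr": (slice(0, _BLOCK), slice(shape[1] - _BLOCK, shape[1])),
        "bl": (slice(shape[0] - _BLOCK, shape[0]), slice(0, _BLOCK)),
        "br": (slice(shape[0] - _BLOCK, shape[0]), slice(shape[1] - _BLOCK, shape[1])),
    }
    if intensity is None:
        return corners["tl"]
    order = sorted(corners.values(), key=lambda sl: float(np.mean(intensity[sl])))
    return order[0]


def distance_markers(binary: np.ndarray, marker_threshold: float = 0.6) -> MarkerImage:
    """Seed markers from the Euclidean distance transform.

    Regions deeper than ``marker_threshold`` times the maximum distance
    become one marker per connected component (labels >= 2); the background
    water hole is a 5x5 block in the top-left corner (or, if the foreground
    reaches it, the emptiest corner).
    """
    if not 0.0 < marker_threshold < 1.0:
        raise InvalidParameterError("marker_threshold must be in (0, 1)")
    fg = np.asarray(binary, dtype=bool)
    labels = np.zeros(fg.shape, dtype=np.int32)

    bg_slices = _corner_block(fg.shape, fg.astype(float))
    labels[bg_slices] = _BACKGROUND_LABEL
    if not fg.any():
        return MarkerImage(labels)

    dist = ndi.distance_transform_edt(fg)
    cores = dist > marker_threshold * dist.max()
    core_labels, n = ndi.label(cores)
    labels[core_labels > 0] = core_labels[core_labels > 0] + _BACKGROUND_LABEL
    return MarkerImage(labels)


def watershed_separate(
    image: np.ndarray, markers: MarkerImage, *, smoothing_sigma: float = 2.0
) -> SegmentationResult:
    """Marker-controlled watershed on the inverted smoothed intensity.

    Fluorescent cells are bright-centred, so basins grow from intensity
    maxima; the boundary lines form along the dim creases between touching
    cells.  Centres are region centroids, one per cell label.
    """
    gray = np.asarray(image, dtype=float)
    if gray.ndim == 3:
        gray = gray.max(axis=2)
    smoothed = ndi.gaussian_filter(gray, smoothing_sigma)
    flooded = watershed(-smoothed, markers=markers.labels)

    # each cell region also sweeps up part of the flat background plateau,
    # so the centre is the intensity-weighted centroid of its region
    weights = smoothed - smoothed.min()
    centers: list[tuple[float, float]] = []
    for lab in range(_BACKGROUND_LABEL + 1, int(markers.labels.max()) + 1):
        region = flooded == lab
        w = weights[region]
        if not region.any() or w.sum() <= 0:
            continue
        ys, xs = np.nonzero(region)
        centers.append((float(np.average(xs, weights=w)), float(np.average(ys, weights=w))))
    return SegmentationResult(labels=flooded, centers=centers, count=len(centers))


def segment_overlapped(
    image: np.ndarray,
    detections: list[Detection],
    group: list[int],
    *,
    channel: str = "red",
    channel_thr: float | None = None,
    clean_radius: int = 2,
    marker_threshold: float = 0.6,
    bbox_margin: float = 0.25,
) -> SegmentationResult:
    """Full separation chain for one overlap group, restricted to the union
    bounding box (plus margin).  Centres are returned in whole-image pixel
    coordinates; a result with fewer regions than detections is flagged as
    under-segmented (reported, never retried)."""
    img = np.asarray(image, dtype=float)
    boxes = [detections[i].bbox for i in group]
    x0 = min(b[0] for b in boxes)
    y0 = min(b[1] for b in boxes)
    x1 = max(b[0] + b[2] for b in boxes)
    y1 = max(b[1] + b[3] for b in boxes)
    mx = int(round((x1 - x0) * bbox_margin))
    my = int(round((y1 - y0) * bbox_margin))
    x0, y0 = max(0, x0 - mx), max(0, y0 - my)
    x1, y1 = min(img.shape[1], x1 + mx), min(img.shape[0], y1 + my)
    crop = img[y0:y1, x0:x1]

    if crop.ndim == 3:
        if channel_thr is None:
            ch = crop[..., _CHANNEL_INDEX[channel]]
            channel_thr = float(threshold_otsu(ch)) if np.ptp(ch) > 0 else 0.0
        mask = channel_threshold(crop, channel, channel_thr)
    else:
        mask = crop

    binary, degenerate = binarize(mask)
    if not degenerate:
        binary = morphology_clean(binary, clean_radius)
    markers = distance_markers(binary, marker_threshold) if binary.any() else MarkerImage(
        np.full(binary.shape, _BACKGROUND_LABEL, dtype=np.int32)
    )
    result = watershed_separate(mask, markers)
    result.centers = [(cx + x0, cy + y0) for cx, cy in result.centers]
    result.under_segmented = result.count < len(group)
    return result
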