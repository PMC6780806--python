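"""Scalable correlation coefficient (SCC) matching.

Cells in suspension sit at different depths, so a single fixed-size template
cannot match them all: defocused cells are larger and blurrier than focused
ones.  SCC matching enlarges a focused original template into a pyramid of
progressively scaled and Gaussian-blurred variants and correlates each
against the image.  Rough locating picks, per target, the variant (the
"optimal size") with the best normalised correlation and emits a bounding
box plus an expanded region of interest for depth detection; precise
locating runs the focused original only, with sub-pixel peak refinement.

The correlation score is the mean-subtracted cross-correlation normalised by
the L2 norms of the mean-subtracted template and window, so it lies in
[-1, 1] and one acceptance threshold transfers across template sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.signal import fftconvolve
from skimage.transform import resize

from .errors import InvalidParameterError
from .imaging_model import OpticsConfig, render_scene, single_cell_scene

__all__ = [
    "Template",
    "TemplateSet",
    "Detection",
    "ROI",
    "correlation_map",
    "build_scalable_templates",
    "rough_locate",
    "precise_locate",
    "make_reference_template",
    "evaluate_detection_rate",
]

_EPS = 1e-10


@dataclass
class Template:
    patch: np.ndarray
    scale_index: int = 0
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        if self.patch.ndim != 2 or min(self.patch.shape) < 3:
            raise InvalidParameterError("template must be 2-D and at least 3x3")

    @property
    def h(self) -> int:
        return self.patch.shape[0]

    @property
    def w(self) -> int:
        return self.patch.shape[1]


@dataclass
class TemplateSet:
    original: Template
    variants: list[Template] = field(default_factory=list)

    def all(self) -> list[Template]:
        return [self.original, *self.variants]


@dataclass
class Detection:
    center_x: float
    center_y: float
    bbox: tuple[int, int, int, int]  # x, y, w, h
    score: float
    scale_index: int
    stage: str  # "rough" | "precise" | "segmented"


@dataclass
class ROI:
    bbox: tuple[int, int, int, int]
    source_detection: int = 0


def correlation_map(image: np.ndarray, template: Template | np.ndarray) -> np.ndarray:
    """Normalised correlation-coefficient map (valid positions only).

    At each placement the template and the image window are mean-subtracted,
    their dot product taken, and the result divided by the product of their
    L2 norms.  Windows (or templates) with zero variance score 0.
    """
    patch = template.patch if isinstance(template, Template) else np.asarray(template, float)
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("correlation_map expects a single-channel image")
    th, tw = patch.shape
    if th > img.shape[0] or tw > img.shape[1]:
        raise InvalidParameterError("template larger than image")

    tp = patch - patch.mean()
    den_t = math.sqrt(float((tp**2).sum()))
    out_shape = (img.shape[0] - th + 1, img.shape[1] - tw + 1)
    if den_t < _EPS:
        return np.zeros(out_shape)

    cross = fftconvolve(img, tp[::-1, ::-1], mode="valid")

    # sliding window sums via integral images
    pad = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    pad[1:, 1:] = np.cumsum(np.cumsum(img, axis=0), axis=1)
    win_sum = pad[th:, tw:] - pad[:-th, tw:] - pad[th:, :-tw] + pad[:-th, :-tw]
    pad2 = np.zeros_like(pad)
    pad2[1:, 1:] = np.cumsum(np.cumsum(img**2, axis=0), axis=1)
    win_sq = pad2[th:, tw:] - pad2[:-th, tw:] - pad2[th:, :-tw] + pad2[:-th, :-tw]
    win_var = np.maximum(win_sq - win_sum**2 / (th * tw), 0.0)

    den = den_t * np.sqrt(win_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > _EPS * den_t, cross / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def build_scalable_templates(
    original: Template,
    n_scales: int = 5,
    size_step: float = 1.15,
    sigma_step: float = 1.0,
) -> TemplateSet:
    """Enlarge the focused original into blurred variants.

    Variant ``k`` is the original resized by ``size_step**k`` with an extra
    Gaussian blur of ``k * sigma_step`` px, emulating a cell defocused by
    ``k`` steps of the working depth range.
    """
    if n_scales < 1:
        raise InvalidParameterError("n_scales must be >= 1")
    variants: list[Template] = []
    prev_h, prev_w = original.h, original.w
    for k in range(1, n_scales + 1):
        factor = size_step**k
        nh = max(prev_h + 1, int(round(original.h * factor)))
        nw = max(prev_w + 1, int(round(original.w * factor)))
        patch = resize(original.patch, (nh, nw), order=1, anti_aliasing=False)
        patch = gaussian_filter(patch, k * sigma_step)
        variants.append(Template(patch=patch, scale_index=k, blur_sigma=k * sigma_step))
        prev_h, prev_w = nh, nw
    return TemplateSet(original=Template(original.patch, 0, original.blur_sigma), variants=variants)


def _local_peaks(r: np.ndarray, threshold: float) -> list[tuple[float, int, int]]:
    """(score, x, y) for strict 3x3 local maxima above threshold, plateau
    ties resolved toward the lexicographically smallest position."""
    if r.size == 0:
        return []
    footprint_max = maximum_filter(r, size=3, mode="constant", cval=-np.inf)
    mask = (r >= threshold) & (r >= footprint_max - 1e-12)
    ys, xs = np.nonzero(mask)
    peaks = [(float(r[y, x]), int(x), int(y)) for y, x in zip(ys, xs)]
    # drop plateau duplicates: keep the smallest (x, y) among adjacent equal peaks
    peaks.sort(key=lambda p: (-p[0], p[1], p[2]))
    kept: list[tuple[float, int, int]] = []
    for s, x, y in peaks:
        if any(abs(x - kx) <= 1 and abs(y - ky) <= 1 for _, kx, ky in kept):
            continue
        kept.append((s, x, y))
    return kept


def _expand_bbox(
    bbox: tuple[int, int, int, int], factor: float, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    x, y, w, h = bbox
    cx, cy = x + (w - 1) / 2.0, y + (h - 1) / 2.0
    nw, nh = int(round(w * factor)), int(round(h * factor))
    nx = int(round(cx - (nw - 1) / 2.0))
    ny = int(round(cy - (nh - 1) / 2.0))
    nx, ny = max(0, nx), max(0, ny)
    nw = min(nw, shape[1] - nx)
    nh = min(nh, shape[0] - ny)
    return (nx, ny, nw, nh)


def rough_locate(
    image: np.ndarray,
    templates: TemplateSet,
    accept_threshold: float = 0.6,
    *,
    roi_margin: float = 1.5,
    nms_radius: float | None = None,
) -> tuple[list[Detection], list[ROI]]:
    """Detect (possibly defocused) targets with the template pyramid.

    Every local correlation maximum above threshold, at every scale, is a
    candidate; greedy non-maximum suppression keeps the best-scoring scale
    per target ("optimal size").  Each detection also yields an ROI expanded
    by ``roi_margin`` for the depth module, since blur grows during the
    defocus sweep.
    """
    img = np.asarray(image, dtype=float)
    candidates: list[tuple[float, float, float, Template]] = []
    for tpl in templates.all():
        if tpl.h > img.shape[0] or tpl.w > img.shape[1]:
            continue
        r = correlation_map(img, tpl)
        for score, x, y in _local_peaks(r, accept_threshold):
            cx, cy = x + (tpl.w - 1) / 2.0, y + (tpl.h - 1) / 2.0
            candidates.append((score, cx, cy, tpl))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3].scale_index))
    detections: list[Detection] = []
    rois: list[ROI] = []
    for score, cx, cy, tpl in candidates:
        radius = nms_radius if nms_radius is not None else tpl.w / 2.0
        if any(math.hypot(cx - d.center_x, cy - d.center_y) <= radius for d in detections):
            continue
        bbox = (
            int(round(cx - (tpl.w - 1) / 2.0)),
            int(round(cy - (tpl.h - 1) / 2.0)),
            tpl.w,
            tpl.h,
        )
        det = Detection(cx, cy, bbox, score, tpl.scale_index, "rough")
        detections.append(det)
        rois.append(ROI(_expand_bbox(bbox, roi_margin, img.shape), len(detections) - 1))
    return detections, rois


def _subpixel_offset(r: np.ndarray, x: int, y: int) -> tuple[float, float]:
    """1-D parabolic refinement along each axis, clamped to +-0.5 px."""

    def refine(vm: float, v0: float, vp: float) -> float:
        den = vm - 2.0 * v0 + vp
        if abs(den) < _EPS:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / den, -0.5, 0.5))

    dx = dy = 0.0
    if 0 < x < r.shape[1] - 1:
        dx = refine(r[y, x - 1], r[y, x], r[y, x + 1])
    if 0 < y < r.shape[0] - 1:
        dy = refine(r[y - 1, x], r[y, x], r[y + 1, x])
    return dx, dy


def precise_locate(
    image: np.ndarray,
    original: Template,
    accept_threshold: float = 0.6,
    *,
    nms_radius: float | None = None,
) -> list[Detection]:
    """Match focused targets with the original template; peak positions are
    refined to sub-pixel accuracy by parabolic interpolation."""
    img = np.asarray(image, dtype=float)
    if original.h > img.shape[0] or original.w > img.shape[1]:
        return []
    r = correlation_map(img, original)
    radius = nms_radius if nms_radius is not None else original.w / 2.0
    detections: list[Detection] = []
    for score, x, y in _local_peaks(r, accept_threshold):
        dx, dy = _subpixel_offset(r, x, y)
        cx = x + dx + (original.w - 1) / 2.0
        cy = y + dy + (original.h - 1) / 2.0
        if any(math.hypot(cx - d.center_x, cy - d.center_y) <= radius for d in detections):
            continue
        bbox = (x, y, original.w, original.h)
        detections.append(Detection(cx, cy, bbox, score, 0, "precise"))
    return detections


def make_reference_template(
    optics: OpticsConfig,
    focused_diameter: float = 16.0,
    peak_intensity: float = 180.0,
    margin_px: int = 4,
) -> Template:
    """Render a noise-free focused cell and crop it — the 'preselected
    focused cell' that seeds the scalable pyramid."""
    fov = (focused_diameter + 2 * margin_px * optics.pixel_size) * 2.0
    scene = single_cell_scene(
        0.0, fov=fov, focused_diameter=focused_diameter, peak_intensity=peak_intensity
    )
    img = render_scene(scene, 0.0, optics, rgb=False, noise=False)
    half = int(round(focused_diameter / (2.0 * optics.pixel_size))) + margin_px
    c = img.pixels.shape[0] // 2
    patch = img.pixels[c - half : c + half + 1, c - half : c + half + 1]
    return Template(patch=patch, scale_index=0, blur_sigma=0.0)


def evaluate_detection_rate(
    optics: OpticsConfig,
    depth_groups: list[float],
    targets_per_group: int = 20,
    seed: int = 0,
    *,
    center_tol_px: float = 5.0,
    accept_threshold: float = 0.6,
    fov_um: float = 128.0,
    focused_diameter: float = 16.0,
) -> tuple[dict[float, float], float]:
    """Correct-detection-rate protocol: one synthetic target per trial at
    the group depth; a trial counts as correct only when exactly one
    detection is returned and its centre lies within ``center_tol_px`` of
    ground truth.  Focused groups (depth 0) use precise locating, defocused
    groups the scalable rough locating.  Returns per-group rates and their
    mean.
    """
    if targets_per_group < 1:
        raise InvalidParameterError("targets_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    reference = make_reference_template(optics, focused_diameter)
    pyramid = build_scalable_templates(reference)
    ps = optics.pixel_size
    margin = focused_diameter * 2.5
    rates: dict[float, float] = {}
    for depth in depth_groups:
        correct = 0
        for trial in range(targets_per_group):
            x = float(rng.uniform(margin, fov_um - margin))
            y = float(rng.uniform(margin, fov_um - margin))
            scene = single_cell_scene(
                depth, fov=fov_um, x=x, y=y, focused_diameter=focused_diameter,
                seed=int(rng.integers(2**31)),
            )
            img = render_scene(scene, 0.0, optics, rgb=False)
            if depth == 0:
                dets = precise_locate(img.pixels, reference, accept_threshold)
            else:
                dets, _ = rough_locate(img.pixels, pyramid, accept_threshold)
            if len(dets) == 1:
                err = math.hypot(dets[0].center_x - x / ps, dets[0].center_y - y / ps)
                if err <= center_tol_px:
                    correct += 1
        rates[depth] = correct / targets_per_group
    return rates, float(np.mean(list(rates.values())))
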