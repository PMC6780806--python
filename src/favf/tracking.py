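"""Neighbourhood-search tracking of the micropipette tip.

The tip is located once (it is brightest when focused), a template is cut
around it, and on every subsequent frame the template is correlated only
inside a neighbourhood search area whose area is three times the template's
— a cost bound that also rejects distant distractors.  Because quenching
and impurity adsorption slowly change the tip's appearance, the template is
refreshed from the newest confident match at a fixed cadence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .planar_locating import Template, correlation_map

__all__ = [
    "TrackState",
    "init_track",
    "track_step",
    "overlapping_rate",
    "evaluate_tracking",
]


@dataclass
class TrackState:
    template: Template
    original_template: Template
    last_bbox: tuple[int, int, int, int]
    search_area: tuple[int, int, int, int]
    last_score: float
    frames_tracked: int = 0
    lost: bool = False


def _search_side(template_side: int, mode: str) -> int:
    """Side length of the search window.  ``area`` mode scales the area by
    3 (side by sqrt(3)); ``side`` mode scales the side by 3."""
    if mode == "area":
        return int(round(template_side * math.sqrt(3.0)))
    if mode == "side":
        return 3 * template_side
    raise InvalidParameterError(f"unknown search mode {mode!r}")


def _centered_bbox(
    cx: float, cy: float, w: int, h: int, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    x = int(round(cx - (w - 1) / 2.0))
    y = int(round(cy - (h - 1) / 2.0))
    x = max(0, min(x, shape[1] - w))
    y = max(0, min(y, shape[0] - h))
    return (x, y, w, h)


def init_track(
    image: np.ndarray,
    tip_xy: tuple[float, float],
    template_size: int = 41,
    *,
    search_mode: str = "area",
) -> TrackState:
    """Cut the original template centred on the tip and create the search
    area around it."""
    img = np.asarray(image, dtype=float)
    tx, ty = tip_xy
    half = template_size // 2
    x0, y0 = int(round(tx)) - half, int(round(ty)) - half
    if x0 < 0 or y0 < 0 or x0 + template_size > img.shape[1] or y0 + template_size > img.shape[0]:
        raise InvalidParameterError("tip too close to the border for this template size")
    patch = img[y0 : y0 + template_size, x0 : x0 + template_size].copy()
    tpl = Template(patch=patch)
    side = _search_side(template_size, search_mode)
    search = _centered_bbox(tx, ty, side, side, img.shape)
    bbox = (x0, y0, template_size, template_size)
    return TrackState(
        template=tpl, original_template=Template(patch.copy()),
        last_bbox=bbox, search_area=search, last_score=1.0,
    )


def track_step(
    image: np.ndarray,
    state: TrackState,
    *,
    update_threshold: float = 0.8,
    update_interval: int = 5,
    lost_threshold: float = 0.3,
    refresh_below: float = 0.95,
    search_mode: str = "area",
) -> TrackState:
    """Advance the track by one frame.

    The current template is correlated inside the search area only; the
    best match re-centres the bounding box and the search area.  A best
    score under ``lost_threshold`` flags the track as lost without moving
    the box.  The template is refreshed from the new match window when the
    appearance has drifted (score below ``refresh_below``) while the match
    is still trustworthy (score at least ``update_threshold``), at most
    every ``update_interval`` frames — refreshing a pristine match would
    only accumulate re-registration drift.
    """
    img = np.asarray(image, dtype=float)
    sx, sy, sw, sh = state.search_area
    window = img[sy : sy + sh, sx : sx + sw]
    tpl = state.template
    if tpl.h > window.shape[0] or tpl.w > window.shape[1]:
        return replace(state, lost=True)
    r = correlation_map(window, tpl)
    flat = int(np.argmax(r))
    py, px = divmod(flat, r.shape[1])
    score = float(r[py, px])
    if score < lost_threshold:
        return replace(state, lost=True, last_score=score)

    x0, y0 = sx + px, sy + py
    bbox = (x0, y0, tpl.w, tpl.h)
    cx, cy = x0 + (tpl.w - 1) / 2.0, y0 + (tpl.h - 1) / 2.0
    side = _search_side(max(tpl.w, tpl.h), search_mode)
    search = _centered_bbox(cx, cy, side, side, img.shape)
    frames = state.frames_tracked + 1
    template = state.template
    if update_threshold <= score < refresh_below and frames % update_interval == 0:
        template = Template(img[y0 : y0 + tpl.h, x0 : x0 + tpl.w].copy())
    return TrackState(
        template=template, original_template=state.original_template,
        last_bbox=bbox, search_area=search, last_score=score,
        frames_tracked=frames, lost=False,
    )


def overlapping_rate(
    bbox_a: tuple[float, float, float, float],
    bbox_b: tuple[float, float, float, float],
) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = bbox_a
    bx, by, bw, bh = bbox_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise InvalidParameterError("boxes must have positive extent")
    iw = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    ih = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / union


def evaluate_tracking(
    frames: list[np.ndarray],
    truth_centers: list[tuple[float, float]],
    accurate_threshold: float = 0.7,
    *,
    template_size: int = 41,
    update_template: bool = True,
) -> float:
    """Fraction of tracked frames whose box overlaps the ground-truth box
    (same size, centred on the true tip) by more than the accuracy
    criterion."""
    if len(frames) < 2:
        raise InvalidParameterError("need at least 2 frames")
    if len(frames) != len(truth_centers):
        raise InvalidParameterError("frames and ground truth lengths differ")
    state = init_track(frames[0], truth_centers[0], template_size)
    accurate = 0
    evaluated = 0
    update_interval = 5 if update_template else 10**9
    for frame, (tx, ty) in zip(frames[1:], truth_centers[1:]):
        state = track_step(frame, state, update_interval=update_interval)
        gt = _centered_bbox(tx, ty, template_size, template_size, frame.shape)
        evaluated += 1
        if not state.lost and overlapping_rate(state.last_bbox, gt) > accurate_threshold:
            accurate += 1
    return accurate / evaluated
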