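"""Multiple depth from defocus (MDFD).

A microscope's shallow depth of field makes a defocused cell appear as a
disc whose blur diameter ``D_n`` grows linearly with its distance from the
focal plane.  Knowing the focused diameter ``D`` and the blur diameters at
two planes separated by a step ``d``, the depth follows from similar
triangles:

    d_n = (D_n - D) / (D_n+1 - D_n) * d.

Two-image depth from defocus cannot tell +z from -z (blur is symmetric
about the focal plane), so MDFD captures *three* images — one step on
either side of a reference plane — and uses the trend of the image contrast
``c`` (max - min of the grayscale profile through the cell centre, the
PGDC) to pick the side: contrast rises toward focus, and an interior
maximum means the focal plane lies inside the bracket (the symmetric case
is screened out).  The focused diameter ``D`` itself is recovered from the
two intersections that the energy-conserving profiles of different planes
share: their width is ``D``.

Per-plane measurement pipeline: grayscale + Gaussian smoothing, k-means
clustering of grey levels (k=3: background, blur edge, cell body), merge
edge+body, morphological clean-up, convex hull, image moments for the
centre, and the width of the cell along the horizontal centre line for
``D_n`` (with sub-pixel refinement at the cluster decision level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import linregress
from skimage.morphology import convex_hull_image

from .errors import (
    DegenerateGeometryError,
    EstimationError,
    InvalidParameterError,
    NegativeBlurError,
    NoCellError,
)
from .imaging_model import (
    CellSpec,
    OpticsConfig,
    Scene,
    model_blur_diameter,
    render_scene,
)

__all__ = [
    "PGDC",
    "BlurMeasurement",
    "DepthEstimate",
    "MdfdConfig",
    "KMeansResult",
    "preprocess_roi",
    "kmeans_segment",
    "extract_cell_region",
    "measure_blur",
    "extract_pgdc",
    "contrast",
    "sharpness_judgement",
    "SharpnessResult",
    "focused_diameter",
    "depth_from_defocus",
    "mdfd_estimate",
    "relative_error",
    "run_error_sweep",
    "measure_blur_series",
    "evaluate_blur_linearity",
    "evaluate_iterative_error",
    "fit_blur_linearity",
    "make_cell_stack_provider",
]


@dataclass
class PGDC:
    """Pixel grayscale distribution curve: the intensity profile along the
    horizontal line through the cell centre."""

    profile: np.ndarray
    center_x: float
    row_y: int


@dataclass
class BlurMeasurement:
    D_n: float  # blur diameter, px
    center: tuple[float, float]
    contrast_c: float
    plane_offset: float = 0.0


@dataclass
class DepthEstimate:
    d_n: float  # estimated depth, µm (signed, relative to the start plane)
    D: float  # experimental focused diameter, px
    measurements: list[BlurMeasurement]
    iterations: int
    status: str  # "focused" | "estimated" | "out_of_range" | "screened"


@dataclass
class SharpnessResult:
    focused_at: int | None
    direction: str  # "toward" | "away"
    screened: bool
    bracket: tuple[int, int] | None = None


@dataclass
class KMeansResult:
    labels: np.ndarray
    centers: np.ndarray
    k_used: int
    reduced: bool = False


@dataclass
class MdfdConfig:
    """Tunables of the iterative depth search."""

    step_um: float = 6.0
    max_iter: int = 6
    focus_tol_um: float = 1.0
    valid_depth_range: float = 40.0
    preprocess_sigma: float = 0.25
    preprocess_sigma_rows: float = 1.0
    kmeans_seed: int = 0
    min_area_px: int = 20
    min_contrast: float = 8.0  # planes below this PGDC contrast carry no signal


def preprocess_roi(
    roi_image: np.ndarray, sigma: float = 0.25, sigma_rows: float | None = None
) -> np.ndarray:
    """Grayscale conversion (channel maximum) followed by Gaussian
    smoothing.

    The filter may be anisotropic: stronger smoothing *across* rows
    (``sigma_rows``) pools the read noise of neighbouring rows without
    blurring the horizontal intensity edges that the blur-diameter
    measurement interpolates, so the width precision improves while the
    linear width-versus-defocus law is left untouched."""
    img = np.asarray(roi_image, dtype=float)
    if img.ndim == 3:
        img = img.max(axis=2)
    if sigma_rows is None:
        sigma_rows = sigma
    if sigma > 0 or sigma_rows > 0:
        img = ndi.gaussian_filter(img, (sigma_rows, sigma))
    return img


def kmeans_segment(gray: np.ndarray, k: int = 3, seed: int = 0) -> KMeansResult:
    """1-D k-means on grey values, quantile-seeded for determinism.

    Labels are ordered by ascending cluster mean, so 0 is background, the
    middle labels the blur edge, and k-1 the cell body.  If the image holds
    fewer distinct values than ``k``, k is reduced and the result flagged.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    arr = np.asarray(gray, dtype=float)
    values = arr.ravel()
    distinct = np.unique(values)
    reduced = distinct.size < k
    k_used = min(k, distinct.size)
    if k_used == 1:
        return KMeansResult(np.zeros(arr.shape, dtype=np.int32), distinct.copy(), 1, True)

    # quantile-seeded Lloyd iterations on the value histogram
    qs = (2.0 * np.arange(k_used) + 1.0) / (2.0 * k_used)
    centers = np.quantile(values, qs)
    centers = np.unique(centers)
    while centers.size < k_used:  # degenerate quantiles: nudge apart
        centers = np.unique(np.concatenate([centers, [centers.max() + 1.0]]))
    uniq, counts = distinct, np.array([np.count_nonzero(values == v) for v in distinct])
    for _ in range(100):
        assign = np.argmin(np.abs(uniq[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k_used):
            sel = assign == j
            if sel.any():
                new[j] = np.average(uniq[sel], weights=counts[sel])
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    centers = centers[order]
    remap = np.empty(k_used, dtype=np.int32)
    remap[order] = np.arange(k_used)
    boundaries = (centers[:-1] + centers[1:]) / 2.0
    labels = np.searchsorted(boundaries, arr).astype(np.int32)
    return KMeansResult(labels, centers, k_used, reduced)


def extract_cell_region(
    labels: KMeansResult | np.ndarray,
    min_area: int = 20,
    *,
    prefer_center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Merge the blur-edge and body clusters, drop small components, and
    return the convex hull of the selected component as the cell mask.

    By default the largest component wins; when ``prefer_center`` (x, y)
    is given — e.g. the centre of an ROI that was cut around a specific
    detection — the qualifying component nearest that point is selected
    instead, so a brighter neighbour inside the ROI cannot hijack the
    measurement."""
    lab = labels.labels if isinstance(labels, KMeansResult) else np.asarray(labels)
    fg = lab >= 1
    if not fg.any():
        raise NoCellError("no foreground cluster")
    comp, n = ndi.label(fg)
    sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    candidates = [i + 1 for i in range(n) if sizes[i] >= min_area]
    if not candidates:
        raise NoCellError("no foreground component above minimum area")
    if prefer_center is None:
        keep = candidates[int(np.argmax([sizes[i - 1] for i in candidates]))]
    else:
        cx, cy = prefer_center
        centroids = ndi.center_of_mass(fg, comp, candidates)
        dists = [np.hypot(c[1] - cx, c[0] - cy) for c in centroids]
        keep = candidates[int(np.argmin(dists))]
    return convex_hull_image(comp == keep)


def _edge_position(profile: np.ndarray, level: float, i0: int, i1: int) -> float:
    """Sub-pixel position where the profile crosses ``level`` between
    adjacent samples i0 (below) and i1 (above).

    The crossing is solved on local quadratics through the two 3-sample
    windows bracketing the pair and the roots averaged; plain linear
    interpolation carries a sampling-phase-dependent bias on the curved
    Gaussian edge that the depth equation (which divides sub-pixel width
    differences) cannot tolerate."""
    a, b = profile[i0], profile[i1]
    if a == b:
        return float(i0)
    lin = i0 + (level - a) / (b - a) * (i1 - i0)
    lo, hi = min(i0, i1), max(i0, i1)
    estimates: list[float] = []
    for pts in ((lo - 1, lo, hi), (lo, hi, hi + 1)):
        if pts[0] < 0 or pts[2] >= profile.size:
            continue
        x = np.array(pts, dtype=float)
        y = profile[list(pts)]
        coef = np.polyfit(x, y, 2)
        roots = np.roots([coef[0], coef[1], coef[2] - level])
        real = [
            r.real
            for r in roots
            if abs(r.imag) < 1e-9 and lo - 0.5 <= r.real <= hi + 0.5
        ]
        if real:
            estimates.append(min(real, key=lambda r: abs(r - lin)))
    if not estimates:
        return lin
    return float(np.mean(estimates))


def _subpixel_width(profile: np.ndarray, level: float) -> float | None:
    """Width of the contiguous region around the profile peak where the
    profile exceeds ``level``, with sub-pixel refinement at the two
    crossings.  Walking outward from the peak (rather than taking global
    extremes) keeps isolated background noise pixels from inflating the
    width."""
    peak = int(np.argmax(profile))
    if profile[peak] < level:
        return None
    left = peak
    while left > 0 and profile[left - 1] >= level:
        left -= 1
    right = peak
    while right < profile.size - 1 and profile[right + 1] >= level:
        right += 1
    lx = _edge_position(profile, level, left - 1, left) if left > 0 else float(left)
    rx = (
        _edge_position(profile, level, right + 1, right)
        if right < profile.size - 1
        else float(right)
    )
    return rx - lx


def measure_blur(
    mask: np.ndarray,
    gray: np.ndarray,
    *,
    level: float | None = None,
    plane_offset: float = 0.0,
) -> BlurMeasurement:
    """Centre (image moments of the mask) and blur diameter ``D_n`` (width
    of the cell along the horizontal centre line).

    When a grey ``level`` is given (the k-means background/edge decision
    boundary), the width is refined to sub-pixel precision by interpolating
    the profile crossings of that level; otherwise the integer mask width
    at the centre row is used.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise NoCellError("empty mask")
    cy, cx = ndi.center_of_mass(m)
    g = np.asarray(gray, dtype=float)
    profile = _row_profile(g, cy)
    row = int(round(min(max(cy, 0), m.shape[0] - 1)))
    if level is not None:
        width = _subpixel_width(profile, level)
    else:
        idx = np.nonzero(m[row])[0]
        width = float(idx[-1] - idx[0] + 1) if idx.size else None
    if width is None or width <= 0:
        raise NoCellError("cell has no extent on the centre row")
    c = contrast(PGDC(profile, cx, row))
    return BlurMeasurement(D_n=float(width), center=(float(cx), float(cy)),
                           contrast_c=c, plane_offset=plane_offset)


def _row_profile(gray: np.ndarray, cy: float) -> np.ndarray:
    """Intensity along the horizontal line at the (fractional) row ``cy``,
    bilinearly interpolated between the two adjacent pixel rows.  Sampling
    the true centre line both removes the chord error of rounding to the
    nearest row and averages two rows of read noise."""
    cy = float(min(max(cy, 0.0), gray.shape[0] - 1))
    r0 = int(math.floor(cy))
    r1 = min(r0 + 1, gray.shape[0] - 1)
    f = cy - r0
    return (1.0 - f) * gray[r0] + f * gray[r1]


def extract_pgdc(gray: np.ndarray, center: tuple[float, float]) -> PGDC:
    """Grayscale profile of the horizontal line through ``center``."""
    g = np.asarray(gray, dtype=float)
    cx, cy = center
    if not (0 <= cx < g.shape[1] and 0 <= cy < g.shape[0]):
        raise InvalidParameterError("center outside image")
    return PGDC(profile=_row_profile(g, cy), center_x=float(cx), row_y=int(round(cy)))


def contrast(pgdc: PGDC | np.ndarray) -> float:
    """Image contrast c: max - min of the profile.  Larger c, clearer
    image."""
    profile = pgdc.profile if isinstance(pgdc, PGDC) else np.asarray(pgdc, float)
    if profile.size == 0:
        raise InvalidParameterError("empty profile")
    return float(profile.max() - profile.min())


def sharpness_judgement(
    c_series: Sequence[float],
    focus_threshold: float | None = None,
    *,
    tol: float = 0.5,
) -> SharpnessResult:
    """Classify the contrast trend over the plane series.

    Contrast rises toward focus and falls away from it, so a series that is
    monotone (by more than ``tol`` grey levels per step) gives the travel
    direction.  Anything else — an interior maximum, or a series flat
    within tolerance — means the focal plane was crossed inside the
    bracket: the symmetric case, flagged ``screened`` together with the
    crossing bracket.
    """
    c = list(c_series)
    if len(c) < 3:
        raise InvalidParameterError("need at least 3 contrast values")
    focused_at = None
    if focus_threshold is not None:
        peak = int(np.argmax(c))
        if c[peak] >= focus_threshold:
            focused_at = peak
    diffs = np.diff(c)
    if np.all(diffs > tol):
        return SharpnessResult(focused_at, "toward", False)
    if np.all(diffs < -tol):
        return SharpnessResult(focused_at, "away", False)
    peak = int(np.argmax(c))
    if 0 < peak < len(c) - 1:
        bracket = (peak - 1, peak + 1)
    else:
        bracket = (0, len(c) - 1)  # flat within tolerance: bracket everything
    direction = "toward" if c[-1] >= c[0] else "away"
    return SharpnessResult(focused_at, direction, True, bracket)


def _pair_intersection_width(
    p1: np.ndarray,
    p2: np.ndarray,
    center_x: float,
    min_value: float | None,
    max_halfwidth: float | None = None,
) -> float | None:
    """Outermost crossing pair of two profiles, or None.

    Only strict sign changes of the difference count, and — when a
    ``min_value`` grey level is given — only crossings where the profiles
    themselves carry signal above it; this rejects the spurious crossings
    that noise produces in the flat background.  ``max_halfwidth`` bounds
    the search radius: the true intersections sit at ±D/2, inside the
    narrowest measured blur diameter.
    """
    diff = p1 - p2
    crossings: list[float] = []
    for i in range(diff.size - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0 or a * b >= 0.0:
            continue
        frac = a / (a - b)
        value = p1[i] + (p1[i + 1] - p1[i]) * frac
        if min_value is not None and value < min_value:
            continue
        if max_halfwidth is not None and abs(i + frac - center_x) > max_halfwidth:
            continue
        crossings.append(i + frac)
    left = [cxx for cxx in crossings if cxx < center_x]
    right = [cxx for cxx in crossings if cxx > center_x]
    if not left or not right:
        return None
    # the true crossings sit symmetrically at +-D/2 about the centre: among
    # near-symmetric pairs take the outermost, else the most symmetric
    pairs = [(l, r) for l in left for r in right]
    asym = lambda p: abs((p[1] - center_x) - (center_x - p[0]))  # noqa: E731
    symmetric = [p for p in pairs if asym(p) <= 3.0]
    if symmetric:
        l, r = max(symmetric, key=lambda p: p[1] - p[0])
    else:
        l, r = min(pairs, key=asym)
    return r - l


def focused_diameter(
    profiles: Sequence[PGDC | np.ndarray],
    center_x: float | None = None,
    *,
    min_value: float | None = None,
    max_width: float | None = None,
) -> float:
    """Focused diameter ``D`` from profile intersections.

    Energy-conserving blur disperses brightness without moving the two
    points where profiles from different planes agree; their spacing is the
    focused diameter.  Profiles must be aligned on the cell centre; with
    more than two, all pairs are averaged.
    """
    if len(profiles) < 2:
        raise InvalidParameterError("need at least 2 profiles")
    arrs: list[np.ndarray] = []
    cx = center_x
    for p in profiles:
        if isinstance(p, PGDC):
            arrs.append(np.asarray(p.profile, float))
            if cx is None:
                cx = p.center_x
        else:
            arrs.append(np.asarray(p, float))
    if cx is None:
        cx = (arrs[0].size - 1) / 2.0
    widths: list[float] = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            if np.max(np.abs(arrs[i] - arrs[j])) < 1e-9:
                continue  # identical profiles carry no crossing information
            half = None if max_width is None else max_width / 2.0 + 1.0
            w = _pair_intersection_width(arrs[i], arrs[j], cx, min_value, half)
            if w is not None:
                widths.append(w)
    if not widths:
        raise EstimationError("no profile intersections found")
    return float(np.mean(widths))


def depth_from_defocus(D: float, D_n: float, D_n1: float, d: float) -> float:
    """Depth from two blur diameters one step apart:
    d_n = (D_n - D) / (D_n1 - D_n) * d."""
    if D_n1 == D_n:
        raise DegenerateGeometryError("blur diameters coincide at both planes")
    if D_n < D:
        raise NegativeBlurError("blur diameter below focused diameter")
    return (D_n - D) / (D_n1 - D_n) * d


def relative_error(d_n: float, d_i: float, D: float) -> float:
    """Relative depth error in percent, with the experimental focused
    diameter as correction factor: e = |d_n - d_i| / (|d_n| + D) * 100."""
    den = abs(d_n) + D
    if den <= 0:
        raise InvalidParameterError("|d_n| + D must be positive")
    return abs(d_n - d_i) / den * 100.0


# ---------------------------------------------------------------------------
# plane measurement and the iterative estimator


def _measure_plane(
    image: np.ndarray, config: MdfdConfig, plane_offset: float = 0.0
) -> tuple[BlurMeasurement, PGDC, float, float] | None:
    """Run the full per-plane pipeline; None when the plane holds no
    recognisable signal.

    Returns (measurement, profile, width level, crossing floor): the width
    level is the background/edge k-means decision boundary at which the
    blur diameter is cut; the crossing floor is a laxer grey level used
    only to reject background-noise crossings when intersecting profiles
    (true intersections can sit well below the width level on strongly
    blurred planes).
    """
    gray = preprocess_roi(image, config.preprocess_sigma, config.preprocess_sigma_rows)
    if float(np.ptp(gray)) < config.min_contrast:
        return None
    km = kmeans_segment(gray, 3, config.kmeans_seed)
    if km.k_used < 2:
        return None
    center = ((gray.shape[1] - 1) / 2.0, (gray.shape[0] - 1) / 2.0)
    try:
        mask = extract_cell_region(km, config.min_area_px, prefer_center=center)
    except NoCellError:
        return None
    # cut level: the background/edge k-means boundary, floored at 15% of
    # the body amplitude — on a crisply focused cell the three clusters
    # split the *background* instead of the blur skirt, which would drop
    # the boundary into the noise
    c_bg, c_top = float(km.centers[0]), float(km.centers[-1])
    level = max(
        float((km.centers[0] + km.centers[1]) / 2.0),
        c_bg + 0.15 * (c_top - c_bg),
    )
    try:
        meas = measure_blur(mask, gray, level=level, plane_offset=plane_offset)
    except NoCellError:
        return None
    if meas.contrast_c < config.min_contrast:
        return None
    pgdc = extract_pgdc(gray, meas.center)
    floor = c_bg + 0.1 * (c_top - c_bg)
    return meas, pgdc, level, floor


def _rewidth(meas: BlurMeasurement, pgdc: PGDC, level: float) -> BlurMeasurement:
    """Re-measure the blur diameter at a common grey level.

    Widths entering one depth estimate must be cut at the *same* level:
    each plane's own k-means boundary shifts slightly as the blur spreads,
    and that shift would contaminate the small width differences the depth
    equation divides by.
    """
    width = _subpixel_width(pgdc.profile, level)
    if width is None:
        return meas
    return BlurMeasurement(D_n=float(width), center=meas.center,
                           contrast_c=meas.contrast_c,
                           plane_offset=meas.plane_offset)


def _align_profiles(pgdcs: list[PGDC]) -> tuple[list[np.ndarray], float]:
    """Resample profiles onto a common axis anchored at each plane's own
    centre, so intersections are taken cell-centre to cell-centre."""
    half = min(
        min(p.center_x, p.profile.size - 1 - p.center_x) for p in pgdcs
    )
    xs = np.arange(-math.floor(half), math.floor(half) + 1, dtype=float)
    out = [
        np.interp(xs, np.arange(p.profile.size) - p.center_x, p.profile)
        for p in pgdcs
    ]
    return out, float(math.floor(half))


def _triple_estimate(
    meas: dict[int, BlurMeasurement], D_hat: float, d: float,
    max_depth: float = 40.0,
) -> tuple[float, float] | None:
    """Signed depth offset of the cell from the middle plane, from blur
    diameters at planes {-1, 0, +1} (spacing ``d``).

    Two geometric regimes: the cell beyond both flanking planes (blur
    changes by alpha*d per step) or inside the bracket (V-shaped blur
    profile).  Both are solved in closed form; the residual against the
    measured diameters picks the regime.  Returns (delta, alpha) or None.
    """
    if not all(k in meas for k in (-1, 0, 1)):
        return _pair_estimate(meas, D_hat, d)
    Dm, D0, Dp = meas[-1].D_n, meas[0].D_n, meas[1].D_n
    t = 1.0 if Dp <= Dm else -1.0  # cell lies on the side with less blur
    D_near = Dp if t > 0 else Dm
    D_opp = Dm if t > 0 else Dp

    candidates: list[tuple[float, float, float]] = []  # (residual, delta, alpha)
    # regime A: |delta| > d, all planes on one side of the cell's focal plane
    alpha_a = (D_opp - D_near) / (2.0 * d)
    if alpha_a > 1e-9 and D0 >= D_hat:
        delta_a = depth_from_defocus(D_hat, D0, D0 + alpha_a * d, d)
        if delta_a <= max_depth:  # a measurable cell lies within the range
            res = _regime_residual(delta_a, alpha_a, D_hat, Dm, D0, Dp, d, t)
            candidates.append((res, delta_a, alpha_a))
    # regime B: |delta| < d, focal plane inside the bracket
    alpha_b = (D_opp + D_near - 2.0 * D_hat) / (2.0 * d)
    if alpha_b > 1e-9:
        delta_b = (D_opp - D_near) / (2.0 * alpha_b)
        if delta_b <= max_depth:
            res = _regime_residual(delta_b, alpha_b, D_hat, Dm, D0, Dp, d, t)
            candidates.append((res, delta_b, alpha_b))
    if not candidates:
        return None
    _, delta, alpha = min(candidates, key=lambda c: c[0])
    return t * max(0.0, delta), alpha


def _regime_residual(
    delta: float, alpha: float, D_hat: float,
    Dm: float, D0: float, Dp: float, d: float, t: float,
) -> float:
    pred = [
        D_hat + alpha * abs(t * delta - s * d) for s in (-1.0, 0.0, 1.0)
    ]
    return float(abs(pred[0] - Dm) + abs(pred[1] - D0) + abs(pred[2] - Dp))


def _pair_estimate(
    meas: dict[int, BlurMeasurement], D_hat: float, d: float
) -> tuple[float, float] | None:
    """Fallback when one flank is unmeasurable (out of the visibility
    range): the cell must lie on the side of the surviving flank."""
    if 0 not in meas:
        return None
    present = [k for k in (-1, 1) if k in meas]
    if not present:
        return None
    k = present[0]
    Dk, D0 = meas[k].D_n, meas[0].D_n
    alpha = (D0 - Dk) / d
    if alpha <= 1e-9 or D0 < D_hat:
        return None
    delta = (D0 - D_hat) / alpha
    return float(k) * delta, alpha


def mdfd_estimate(
    stack_provider: Callable[[float], np.ndarray],
    roi: tuple[int, int, int, int] | None = None,
    d: float = 6.0,
    config: MdfdConfig | None = None,
) -> DepthEstimate:
    """Iterative MDFD: bracket the current plane with images at ±d, judge
    the contrast trend, estimate the cell's offset with the depth equation,
    move the plane, and repeat until focused.

    ``stack_provider`` maps a requested image-plane position (µm, relative
    to the starting plane) to an image; ``roi`` optionally crops it.  The
    estimate converges in two or three iterations on clean data.  Cells
    whose estimate leaves the valid fluorescence range — or which are never
    measurable at all — are reported ``out_of_range``.
    """
    cfg = config or MdfdConfig()
    if d <= 0:
        raise InvalidParameterError("step interval d must be positive")

    def grab(z: float) -> np.ndarray:
        img = np.asarray(stack_provider(z))
        if roi is not None:
            x, y, w, h = roi
            img = img[y : y + h, x : x + w]
        return img

    f = 0.0
    measurements: list[BlurMeasurement] = []
    D_hat = float("nan")
    status = "estimated"
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        planes = {s: f + s * d for s in (-1, 0, 1)}
        found: dict[int, BlurMeasurement] = {}
        found_pgdc: dict[int, PGDC] = {}
        levels: list[float] = []
        floors: list[float] = []
        for s, z in planes.items():
            res = _measure_plane(grab(z), cfg, plane_offset=z)
            if res is not None:
                found[s] = res[0]
                found_pgdc[s] = res[1]
                levels.append(res[2])
                floors.append(res[3])
        if levels:  # cut all widths of this triple at one common level
            common = min(levels)
            found = {s: _rewidth(m, found_pgdc[s], common) for s, m in found.items()}
        pgdcs = [found_pgdc[s] for s in sorted(found_pgdc)]
        measurements.extend(found.values())
        if not found:
            if iterations == 1:
                return DepthEstimate(
                    d_n=math.copysign(cfg.valid_depth_range + d, f if f else 1.0),
                    D=D_hat, measurements=measurements,
                    iterations=iterations, status="out_of_range",
                )
            break

        if len(pgdcs) >= 2:
            aligned, _ = _align_profiles(pgdcs)
            try:
                D_new = focused_diameter(
                    aligned,
                    center_x=(aligned[0].size - 1) / 2.0,
                    min_value=min(floors),
                    max_width=min(m.D_n for m in found.values()) + 2.0,
                )
                if math.isnan(D_hat):
                    D_hat = D_new
                elif abs(D_new - D_hat) <= 0.2 * D_hat:
                    D_hat = 0.5 * (D_hat + D_new)
                # near focus the profiles nearly coincide and their
                # crossings turn unreliable; a >20% jump is discarded
            except EstimationError:
                pass
        if math.isnan(D_hat):
            # no intersections: profiles nearly identical => essentially focused
            status = "focused"
            break

        est = _triple_estimate(found, D_hat, d, max_depth=cfg.valid_depth_range)
        if est is None:
            status = "focused" if 0 in found and found[0].D_n <= D_hat * 1.05 else "estimated"
            break
        delta, _alpha = est
        # one hop is never trusted beyond half the visibility range: a cell
        # measurable at the current plane cannot be farther than the range,
        # and unbounded hops (e.g. from an ROI holding two cells at
        # different depths) would otherwise diverge
        half_range = cfg.valid_depth_range / 2.0
        delta = float(np.clip(delta, -half_range, half_range))
        if abs(f + delta) > cfg.valid_depth_range:
            # the cell is still measurable from the current plane, so a
            # hop beyond the visibility range is a measurement
            # inconsistency (e.g. a second cell in the ROI), not a cell
            # out of range: stop here rather than diverge
            status = "estimated"
            break
        f += delta
        if abs(delta) < cfg.focus_tol_um:
            status = "focused"
            break
    return DepthEstimate(d_n=f, D=D_hat, measurements=measurements,
                         iterations=iterations, status=status)


# ---------------------------------------------------------------------------
# evaluation protocols


def make_cell_stack_provider(
    cell_depth: float,
    optics: OpticsConfig,
    *,
    fov_um: float = 96.0,
    focused_diameter: float = 16.0,
    peak_intensity: float = 180.0,
    xy_jitter: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    noise: bool = True,
) -> Callable[[float], np.ndarray]:
    """Virtual z-drive for one cell: returns a callable mapping an
    image-plane position (µm) to a rendered grayscale frame."""
    cell = CellSpec(
        id=0,
        x=fov_um / 2.0 + xy_jitter[0],
        y=fov_um / 2.0 + xy_jitter[1],
        z=cell_depth,
        focused_diameter=focused_diameter,
        peak_intensity=peak_intensity,
    )
    scene = Scene(cells=[cell], fov_width=fov_um, fov_height=fov_um, rng_seed=seed)

    def provider(z: float) -> np.ndarray:
        return render_scene(scene, z, optics, rgb=False, noise=noise).pixels

    return provider


def run_error_sweep(
    optics: OpticsConfig,
    d_i_list: Sequence[float],
    d_list: Sequence[float],
    n_cells: int = 10,
    seed: int = 0,
    *,
    config: MdfdConfig | None = None,
    noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass depth accuracy over a grid of initial depths and step
    intervals.

    For each (d_i, d) pair and each of ``n_cells`` synthetic cells, two
    images are captured moving away from the focal plane — at defocus d_i
    and d_i + d — the focused diameter is taken from their profile
    intersections, and the depth equation gives a one-shot estimate whose
    relative error is averaged.  Pairs that would require imaging beyond
    the valid fluorescence range are recorded as out of range (OOR), as are
    estimates that land outside it.

    Returns (mean error table in %, OOR fraction table), rows d_i, columns
    d.
    """
    if not d_i_list or not d_list:
        raise InvalidParameterError("d_i_list and d_list must be non-empty")
    cfg = config or MdfdConfig()
    rng = np.random.default_rng(seed)
    cell_seeds = rng.integers(2**31, size=n_cells)
    jitters = rng.uniform(-0.5, 0.5, size=(n_cells, 2))
    diam_jit = rng.uniform(-1.0, 1.0, size=n_cells)

    errors = pd.DataFrame(index=list(d_i_list), columns=list(d_list), dtype=float)
    oor = pd.DataFrame(0.0, index=list(d_i_list), columns=list(d_list))
    for d_i in d_i_list:
        for d in d_list:
            es: list[float] = []
            n_oor = 0
            for c in range(n_cells):
                diam = 16.0 + float(diam_jit[c])
                provider = make_cell_stack_provider(
                    d_i, optics, focused_diameter=diam,
                    xy_jitter=tuple(jitters[c]), seed=int(cell_seeds[c]),
                    noise=noise,
                )
                if d_i + d > cfg.valid_depth_range:
                    n_oor += 1
                    continue
                # two planes moving away from focus: defocus d_i and d_i + d
                m0 = _measure_plane(provider(0.0), cfg, 0.0)
                m1 = _measure_plane(provider(-d), cfg, -d)
                if m0 is None or m1 is None:
                    n_oor += 1
                    continue
                common = min(m0[2], m1[2])
                b0 = _rewidth(m0[0], m0[1], common)
                b1 = _rewidth(m1[0], m1[1], common)
                aligned, _ = _align_profiles([m0[1], m1[1]])
                try:
                    D_hat = focused_diameter(
                        aligned,
                        center_x=(aligned[0].size - 1) / 2.0,
                        min_value=min(m0[3], m1[3]),
                        max_width=min(b0.D_n, b1.D_n) + 2.0,
                    )
                    d_n = depth_from_defocus(D_hat, b0.D_n, b1.D_n, d)
                except (EstimationError, DegenerateGeometryError, NegativeBlurError):
                    n_oor += 1
                    continue
                if abs(d_n) > cfg.valid_depth_range:
                    n_oor += 1
                    continue
                es.append(relative_error(d_n, d_i, D_hat * optics.pixel_size))
            errors.loc[d_i, d] = float(np.mean(es)) if es else float("nan")
            oor.loc[d_i, d] = n_oor / n_cells
    return errors, oor


def measure_blur_series(
    stack_provider: Callable[[float], np.ndarray],
    planes: Sequence[float],
    config: MdfdConfig | None = None,
) -> list[tuple[float, float]]:
    """Blur diameters of one cell across a defocus series.

    All planes of the series are cut at one common grey level (the lowest
    of the per-plane background/edge boundaries), since widths that enter
    one fit or one depth equation must share their reference level.
    Returns (plane position, D_n) pairs for the measurable planes.
    """
    cfg = config or MdfdConfig()
    results = []
    for z in planes:
        res = _measure_plane(np.asarray(stack_provider(z)), cfg, plane_offset=z)
        if res is not None:
            results.append((z, res))
    if not results:
        return []
    common = min(r[2] for _, r in results)
    return [
        (z, _rewidth(r[0], r[1], common).D_n) for z, r in results
    ]


def evaluate_blur_linearity(
    optics: OpticsConfig,
    n_cells: int = 10,
    planes: Sequence[float] = (2.0, 5.0, 9.0, 12.0, 16.0, 20.0),
    seed: int = 0,
    *,
    config: MdfdConfig | None = None,
) -> tuple[list[float], float]:
    """Linearity protocol: fit blur diameter against image-plane depth for
    ``n_cells`` synthetic cells imaged at unequally spaced planes within
    the precise working range; returns per-cell R^2 and their mean."""
    cfg = config or MdfdConfig()
    rng = np.random.default_rng(seed)
    r2s: list[float] = []
    for _ in range(n_cells):
        provider = make_cell_stack_provider(
            0.0,
            optics,
            seed=int(rng.integers(2**31)),
            focused_diameter=16.0 + float(rng.uniform(-1.0, 1.0)),
            xy_jitter=tuple(rng.uniform(-0.5, 0.5, 2)),
        )
        points = measure_blur_series(provider, planes, cfg)
        if len(points) >= 3:
            r2s.append(fit_blur_linearity(points)[2])
    return r2s, float(np.mean(r2s)) if r2s else float("nan")


def evaluate_iterative_error(
    optics: OpticsConfig,
    n_cells: int = 10,
    d: float = 6.0,
    seed: int = 0,
    *,
    d_i_range: tuple[float, float] = (4.0, 20.0),
    config: MdfdConfig | None = None,
) -> tuple[list[float], float, float]:
    """Convergent-regime protocol: run the iterative estimator to focus for
    cells at random initial depths and score each with the relative-error
    formula.  Returns per-cell errors (%), their mean, and the mean
    iteration count."""
    cfg = config or MdfdConfig()
    rng = np.random.default_rng(seed)
    errors: list[float] = []
    iters: list[int] = []
    for _ in range(n_cells):
        d_i = float(rng.uniform(*d_i_range)) * (1.0 if rng.uniform() < 0.5 else -1.0)
        provider = make_cell_stack_provider(
            d_i,
            optics,
            seed=int(rng.integers(2**31)),
            focused_diameter=16.0 + float(rng.uniform(-1.0, 1.0)),
            xy_jitter=tuple(rng.uniform(-0.5, 0.5, 2)),
        )
        est = mdfd_estimate(provider, d=d, config=cfg)
        errors.append(relative_error(est.d_n, d_i, est.D * optics.pixel_size))
        iters.append(est.iterations)
    return errors, float(np.mean(errors)), float(np.mean(iters))


def fit_blur_linearity(
    measurements: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS line through (depth, D_n) points; returns (slope, intercept,
    R^2)."""
    if len(measurements) < 3:
        raise InvalidParameterError("need at least 3 points")
    depths = np.array([m[0] for m in measurements], dtype=float)
    dns = np.array([m[1] for m in measurements], dtype=float)
    if np.ptp(depths) == 0:
        raise InvalidParameterError("all depths identical")
    res = linregress(depths, dns)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
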