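"""Synthetic fluorescence-microscope renderer.

The virtual microscope implements the thin-lens defocus model used throughout
the package: a cell is a uniform fluorescent disc of focused diameter ``D``
(µm); when the image plane sits ``|z|`` µm from the cell's focal plane, the
apparent blur diameter grows linearly,

    D_n = D + blur_slope * pixel_size * |z|,

and the observed image is the focused disc convolved with a 2-D Gaussian
point-spread function whose spread ``sigma`` is proportional to the blur
growth ``D_n - D``.  The convolution kernel integrates to one, so the total
brightness energy of a cell is conserved under defocus — it is only
dispersed.  Beyond ``valid_depth_range`` the fluorescence signal is too weak
to recognise and the cell is rendered below the detectability floor.

Coordinates: pixel origin top-left, x to the right, y down, 0-based.  Depth
``z`` is signed and measured relative to the focal plane; images at ``+z``
and ``-z`` are identical for a centred cell (the symmetry ambiguity that the
depth module must resolve is real in this simulator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .errors import GenerationError, InvalidParameterError

__all__ = [
    "OpticsConfig",
    "CellSpec",
    "PipetteSpec",
    "Scene",
    "FluorescenceImage",
    "DefocusStack",
    "gaussian_psf",
    "model_blur_diameter",
    "render_scene",
    "render_defocus_stack",
    "make_mixture_scene",
    "make_cluster_scene",
    "single_cell_scene",
    "simulate_tip_sequence",
]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class OpticsConfig:
    """Virtual microscope parameters.

    Parameters
    ----------
    pixel_size:
        Camera sampling, µm per pixel.
    blur_slope:
        Growth of the blur diameter per µm of defocus, px/µm.  Together with
        ``pixel_size`` this fixes the linear blur law.
    psf_sigma_per_blur:
        Dimensionless factor mapping the blur growth ``D_n - D`` to the
        Gaussian PSF spread: ``sigma = psf_sigma_per_blur * (D_n - D) / 2``.
        The default is calibrated so that the diameter recovered by the
        depth module's measurement pipeline tracks the model ``D_n``.
    valid_depth_range:
        µm beyond which fluorescence is too weak to recognise.
    noise_sigma:
        Additive Gaussian read-noise, grey levels.
    background_level:
        Constant background, grey levels.
    """

    pixel_size: float = 1.0
    blur_slope: float = 0.4
    psf_sigma_per_blur: float = 1.25
    valid_depth_range: float = 40.0
    noise_sigma: float = 1.0
    background_level: float = 8.0
    max_grayscale: float = 255.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.blur_slope <= 0:
            raise InvalidParameterError("blur_slope must be positive")
        if self.valid_depth_range <= 0:
            raise InvalidParameterError("valid_depth_range must be positive")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be non-negative")

    def psf_sigma_px(self, blur_diameter_um: float, focused_diameter_um: float) -> float:
        """PSF spread (px) for a given blur diameter."""
        growth = max(0.0, blur_diameter_um - focused_diameter_um)
        return self.psf_sigma_per_blur * growth / 2.0 / self.pixel_size


@dataclass(frozen=True)
class CellSpec:
    """A fluorescent cell: planar position and signed depth in µm."""

    id: int
    x: float
    y: float
    z: float
    focused_diameter: float = 16.0
    color: str = "red"
    peak_intensity: float = 180.0

    def __post_init__(self) -> None:
        if self.focused_diameter <= 0:
            raise InvalidParameterError("focused_diameter must be positive")
        if self.peak_intensity < 0:
            raise InvalidParameterError("peak_intensity must be non-negative")
        if self.color not in ("red", "green"):
            raise InvalidParameterError(f"unknown cell color {self.color!r}")


@dataclass(frozen=True)
class PipetteSpec:
    """Micropipette pose: tip position (µm) and shaft direction."""

    tip_x: float
    tip_y: float
    tip_z: float = 0.0
    shaft_angle: float = 30.0
    color: str = "red"
    width: float = 19.0
    peak_intensity: float = 220.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("pipette width must be positive")


@dataclass
class Scene:
    """World model: cells, optional pipette, field of view in µm."""

    cells: list[CellSpec]
    fov_width: float
    fov_height: float
    pipette: PipetteSpec | None = None
    rng_seed: int = 0


@dataclass
class FluorescenceImage:
    """A rendered frame.  ``pixels`` is (H, W) or (H, W, 3) float64 in
    grey-level units, clipped to [0, max_grayscale]."""

    pixels: np.ndarray
    pixel_size: float
    z_plane: float

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def channel(self, name: str) -> np.ndarray:
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels[..., _CHANNEL_INDEX[name]]

    def to_gray(self) -> np.ndarray:
        """Collapse channels by maximum — appropriate for fluorescence,
        where each object emits in a single channel."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.max(axis=2)


@dataclass
class DefocusStack:
    """Images of one field captured at successive image-plane offsets."""

    images: list[FluorescenceImage]
    step_interval: float
    z_offsets: list[float]


def gaussian_psf(sigma: float, support_radius: int | None = None) -> np.ndarray:
    """Discrete 2-D Gaussian kernel, normalised to unit sum.

    ``sigma = 0`` returns the single-entry identity kernel.  The support
    defaults to four sigma, enough to keep truncation below 1e-4 of the
    energy.
    """
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    if sigma == 0:
        return np.ones((1, 1))
    if support_radius is None:
        support_radius = max(1, int(math.ceil(4.0 * sigma)))
    if support_radius < 1:
        raise InvalidParameterError("support_radius must be >= 1")
    ax = np.arange(-support_radius, support_radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    kernel = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return kernel / kernel.sum()


def model_blur_diameter(cell: CellSpec, optics: OpticsConfig, focal_z: float = 0.0) -> float:
    """Ground-truth blur diameter (µm) of ``cell`` seen from ``focal_z``.

    This closed form is the oracle against which the measurement pipeline
    is validated: D_n = D + blur_slope * pixel_size * |z - focal_z|.
    """
    defocus = abs(cell.z - focal_z)
    return cell.focused_diameter + optics.blur_slope * optics.pixel_size * defocus


_SUPERSAMPLE = 4  # sub-pixel grid for disc rendering and PSF convolution


def _disc_patch(radius_px: float, fx: float, fy: float, pad: int) -> np.ndarray:
    """Anti-aliased uniform disc of radius ``radius_px`` centred at the
    fractional offset (fx, fy) inside a padded square patch."""
    half = int(math.ceil(radius_px)) + pad
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax - fx, ax - fy)
    dist = np.hypot(xx, yy)
    return np.clip(radius_px + 0.5 - dist, 0.0, 1.0)


def _disc_blur_patch(
    radius_px: float, fx: float, fy: float, pad: int, sigma_px: float
) -> np.ndarray:
    """Uniform disc convolved with a Gaussian PSF, evaluated on a
    supersampled grid and box-binned back to the pixel grid, so the edge
    profile is the physical one rather than a rasterisation artefact.  The
    unit-sum kernel and the exact binning conserve the disc's integrated
    intensity."""
    s = _SUPERSAMPLE
    half = int(math.ceil(radius_px)) + pad
    n = (2 * half + 1) * s
    # supersample centres: pixel p covers [p-0.5, p+0.5); subpixels at
    # p - 0.5 + (j + 0.5)/s
    ax = (np.arange(n) + 0.5) / s - 0.5 - half
    xx, yy = np.meshgrid(ax - fx, ax - fy)
    dist = np.hypot(xx, yy)
    fine = np.clip((radius_px + 0.5 / s - dist) * s, 0.0, 1.0)
    if sigma_px > 0:
        kernel = gaussian_psf(sigma_px * s)
        fine = fftconvolve(fine, kernel, mode="same")
    return fine.reshape(2 * half + 1, s, 2 * half + 1, s).mean(axis=(1, 3))


def _segment_patch(
    length_px: float, half_width_px: float, angle_deg: float, fx: float, fy: float, pad: int
) -> np.ndarray:
    """Anti-aliased thick segment (round caps) starting at the patch centre
    and extending ``length_px`` in direction ``angle_deg``."""
    half = int(math.ceil(length_px + half_width_px)) + pad
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax - fx, ax - fy)
    theta = math.radians(angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    # distance from each pixel to the segment [0, L] * (ux, uy)
    t = np.clip(xx * ux + yy * uy, 0.0, length_px)
    dist = np.hypot(xx - t * ux, yy - t * uy)
    return np.clip(half_width_px + 0.5 - dist, 0.0, 1.0)


def _add_patch(canvas: np.ndarray, patch: np.ndarray, cx: int, cy: int) -> None:
    """Accumulate ``patch`` (odd square) centred at integer (cx, cy),
    clipping at the canvas borders."""
    half = patch.shape[0] // 2
    h, w = canvas.shape
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    py0, px0 = max(0, -y0), max(0, -x0)
    py1 = patch.shape[0] - max(0, y1 - h)
    px1 = patch.shape[1] - max(0, x1 - w)
    if py0 >= py1 or px0 >= px1:
        return
    canvas[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] += patch[py0:py1, px0:px1]


def _blur_patch(patch: np.ndarray, sigma_px: float) -> np.ndarray:
    if sigma_px <= 0:
        return patch
    kernel = gaussian_psf(sigma_px)
    return fftconvolve(patch, kernel, mode="same")


def _noise_rng(scene: Scene, focal_z: float, salt: int = 0) -> np.random.Generator:
    # deterministic per (seed, plane): identical seed + config => identical image
    z_key = int(round(focal_z * 1000.0)) % (2**31)
    return np.random.default_rng([scene.rng_seed % (2**31), z_key, salt % (2**31)])


def render_scene(
    scene: Scene,
    focal_z: float,
    optics: OpticsConfig,
    *,
    rgb: bool = True,
    noise: bool = True,
) -> FluorescenceImage:
    """Render the scene as seen with the image plane at ``focal_z``.

    Each cell is drawn as an anti-aliased focused disc and convolved with
    the unit-sum Gaussian PSF implied by its defocus, so the integrated
    intensity of a cell (before noise and clipping) does not depend on
    ``focal_z`` within the valid range.  Cells defocused beyond
    ``valid_depth_range`` are attenuated below the detectability floor.
    """
    ps = optics.pixel_size
    h = int(round(scene.fov_height / ps))
    w = int(round(scene.fov_width / ps))
    channels = np.zeros((3, h, w))

    for cell in scene.cells:
        defocus = abs(cell.z - focal_z)
        d_n = model_blur_diameter(cell, optics, focal_z)
        sigma = optics.psf_sigma_px(d_n, cell.focused_diameter)
        radius_px = cell.focused_diameter / (2.0 * ps)
        cx_f, cy_f = cell.x / ps, cell.y / ps
        cx, cy = int(round(cx_f)), int(round(cy_f))
        pad = int(math.ceil(4.0 * sigma)) + 2
        patch = (
            _disc_blur_patch(radius_px, cx_f - cx, cy_f - cy, pad, sigma)
            * cell.peak_intensity
        )
        if defocus > optics.valid_depth_range:
            # fluorescence too weak to recognise: scale peak to the noise floor
            floor = optics.noise_sigma if optics.noise_sigma > 0 else 0.0
            peak = patch.max()
            patch = patch * (floor / peak if peak > 0 else 0.0)
        _add_patch(channels[_CHANNEL_INDEX[cell.color]], patch, cx, cy)

    if scene.pipette is not None:
        pip = scene.pipette
        defocus = abs(pip.tip_z - focal_z)
        d_n = pip.width + optics.blur_slope * ps * defocus
        sigma = optics.psf_sigma_px(d_n, pip.width)
        half_width_px = pip.width / (2.0 * ps)
        tx_f, ty_f = pip.tip_x / ps, pip.tip_y / ps
        tx, ty = int(round(tx_f)), int(round(ty_f))
        length_px = float(np.hypot(h, w))  # shaft runs out of the frame
        pad = int(math.ceil(4.0 * sigma)) + 2
        patch = (
            _segment_patch(length_px, half_width_px, pip.shaft_angle, tx_f - tx, ty_f - ty, pad)
            * pip.peak_intensity
        )
        patch = _blur_patch(patch, sigma)
        if defocus > optics.valid_depth_range:
            peak = patch.max()
            floor = optics.noise_sigma if optics.noise_sigma > 0 else 0.0
            patch = patch * (floor / peak if peak > 0 else 0.0)
        _add_patch(channels[_CHANNEL_INDEX[pip.color]], patch, tx, ty)

    channels += optics.background_level
    if noise and optics.noise_sigma > 0:
        rng = _noise_rng(scene, focal_z)
        channels += rng.normal(0.0, optics.noise_sigma, size=channels.shape)
    np.clip(channels, 0.0, optics.max_grayscale, out=channels)

    pixels = np.moveaxis(channels, 0, 2) if rgb else channels.max(axis=0)
    return FluorescenceImage(pixels=pixels, pixel_size=ps, z_plane=focal_z)


def render_defocus_stack(
    scene: Scene,
    start_z: float,
    step: float,
    count: int,
    optics: OpticsConfig,
    *,
    rgb: bool = True,
    noise: bool = True,
) -> DefocusStack:
    """Render ``count`` images at ``start_z + k*step`` for k = 0..count-1."""
    if count < 2:
        raise InvalidParameterError("a defocus stack needs at least 2 planes")
    if step == 0:
        raise InvalidParameterError("step must be non-zero")
    offsets = [start_z + k * step for k in range(count)]
    images = [render_scene(scene, z, optics, rgb=rgb, noise=noise) for z in offsets]
    return DefocusStack(images=images, step_interval=step, z_offsets=offsets)


def single_cell_scene(
    z: float,
    fov: float = 96.0,
    *,
    x: float | None = None,
    y: float | None = None,
    focused_diameter: float = 16.0,
    peak_intensity: float = 180.0,
    color: str = "red",
    seed: int = 0,
) -> Scene:
    """One centred (or explicitly placed) cell — the workhorse fixture for
    depth and locating tests."""
    cx = fov / 2.0 if x is None else x
    cy = fov / 2.0 if y is None else y
    cell = CellSpec(
        id=0, x=cx, y=cy, z=z,
        focused_diameter=focused_diameter,
        peak_intensity=peak_intensity, color=color,
    )
    return Scene(cells=[cell], fov_width=fov, fov_height=fov, rng_seed=seed)


def make_cluster_scene(
    k: int,
    spacing_radii: tuple[float, float] = (1.8, 2.0),
    seed: int = 0,
    *,
    fov: float = 128.0,
    focused_diameter: float = 16.0,
    color: str = "red",
) -> Scene:
    """A cluster of ``k`` touching/overlapping cells around the field
    centre.

    Adjacent centres are ``spacing_radii`` cell radii apart (< 2 radii
    means intersecting footprints), and a minimum pairwise spacing equal to
    the lower bound is enforced by rejection, since cells closer than
    ~1.7 radii merge into a single distance-transform core and are not
    separable by the marker scheme.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    rng = np.random.default_rng(seed)
    r = focused_diameter / 2.0
    for _attempt in range(200):
        cells = [(fov / 2.0, fov / 2.0)]
        angle = rng.uniform(0.0, 2.0 * math.pi)
        ok = True
        for _i in range(1, k):
            placed = False
            for _try in range(50):
                s = rng.uniform(*spacing_radii) * r
                a = angle + rng.uniform(-0.9, 0.9) + 2.0 * math.pi / max(2, k)
                nx = cells[-1][0] + s * math.cos(a)
                ny = cells[-1][1] + s * math.sin(a)
                if all(
                    math.hypot(nx - cx, ny - cy) >= spacing_radii[0] * r * 0.999
                    for cx, cy in cells
                ) and focused_diameter < nx < fov - focused_diameter and (
                    focused_diameter < ny < fov - focused_diameter
                ):
                    cells.append((nx, ny))
                    angle = a
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            specs = [
                CellSpec(id=i, x=cx, y=cy, z=0.0,
                         focused_diameter=focused_diameter, color=color)
                for i, (cx, cy) in enumerate(cells)
            ]
            return Scene(cells=specs, fov_width=fov, fov_height=fov, rng_seed=seed)
    raise GenerationError(f"could not place a {k}-cell cluster")


def make_mixture_scene(
    n_target: int,
    ratio: float = 100.0,
    fov: tuple[float, float] = (400.0, 400.0),
    overlap_fraction: float = 0.0,
    seed: int = 0,
    *,
    z_range: tuple[float, float] = (-15.0, 15.0),
    focused_diameter: float = 16.0,
    target_peak: float = 180.0,
    background_peak: float = 180.0,
) -> Scene:
    """Two-colour mixture: ``n_target`` red target cells plus
    ``round(ratio * n_target)`` green background cells placed uniformly.

    A fraction ``overlap_fraction`` of the targets is given a touching
    neighbour (drawn from the green population when available, otherwise
    another target) to exercise the segmentation path.  Deterministic for a
    fixed seed.
    """
    if n_target < 0:
        raise InvalidParameterError("n_target must be >= 0")
    if ratio <= 0:
        raise InvalidParameterError("ratio must be positive")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise InvalidParameterError("overlap_fraction must be in [0, 1]")
    fov_w, fov_h = fov
    n_green = int(round(ratio * n_target))
    n_total = n_target + n_green
    cell_area = math.pi * (focused_diameter / 2.0) ** 2
    if n_total * cell_area > 0.5 * fov_w * fov_h:
        raise GenerationError(
            f"{n_total} cells of diameter {focused_diameter} µm cannot fit a "
            f"{fov_w}x{fov_h} µm field"
        )
    rng = np.random.default_rng(seed)
    margin = focused_diameter
    cells: list[CellSpec] = []

    def _place(i: int, color: str, peak: float) -> CellSpec:
        return CellSpec(
            id=i,
            x=float(rng.uniform(margin, fov_w - margin)),
            y=float(rng.uniform(margin, fov_h - margin)),
            z=float(rng.uniform(*z_range)),
            focused_diameter=focused_diameter,
            color=color,
            peak_intensity=peak,
        )

    for i in range(n_target):
        cells.append(_place(i, "red", target_peak))
    for i in range(n_green):
        cells.append(_place(n_target + i, "green", background_peak))

    # move companions next to the first k targets so their footprints touch
    k = int(round(overlap_fraction * n_target))
    for j in range(k):
        target = cells[j]
        companion_idx = n_target + j if n_green > j else (j + 1) % max(1, n_target)
        if companion_idx == j:
            break
        comp = cells[companion_idx]
        angle = rng.uniform(0.0, 2.0 * math.pi)
        dist = rng.uniform(0.5, 0.9) * (target.focused_diameter + comp.focused_diameter) / 2.0
        cells[companion_idx] = replace(
            comp,
            x=float(np.clip(target.x + dist * math.cos(angle), margin, fov_w - margin)),
            y=float(np.clip(target.y + dist * math.sin(angle), margin, fov_h - margin)),
            z=target.z,
        )
    return Scene(cells=cells, fov_width=fov_w, fov_height=fov_h, rng_seed=seed)


def simulate_tip_sequence(
    n_frames: int,
    optics: OpticsConfig,
    *,
    speed_um_per_frame: float = 5.0,
    frame_um: float = 160.0,
    template_size_px: int = 41,
    fade_per_frame: float = 0.9998,
    width_growth_um_per_frame: float = 0.0,
    angle_drift_deg_per_frame: float = 0.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """Render a pipette tip wandering at a fixed per-frame speed.

    The heading performs a persistent random walk and reflects off a border
    margin; the emission intensity fades geometrically per frame (emulating
    fluorescence quenching) and the apparent tip width may grow slowly
    (emulating impurity adsorption).  Returns the red-channel frames and
    the ground-truth tip position (px) per frame.  A slow shaft rotation
    about the tip exercises appearance drift that leaves the tip position
    unchanged.
    """
    rng = np.random.default_rng(seed)
    ps = optics.pixel_size
    margin = (template_size_px * ps) * 1.2
    x = frame_um / 2.0
    y = frame_um / 2.0
    heading = rng.uniform(0.0, 2.0 * math.pi)
    intensity = 220.0
    width = 19.0
    angle = 30.0
    frames: list[np.ndarray] = []
    truth: list[tuple[float, float]] = []
    for i in range(n_frames):
        pip = PipetteSpec(tip_x=x, tip_y=y, tip_z=0.0, shaft_angle=angle,
                          width=width, peak_intensity=intensity)
        scene = Scene(cells=[], fov_width=frame_um, fov_height=frame_um,
                      pipette=pip, rng_seed=seed + i)
        img = render_scene(scene, 0.0, optics, rgb=False)
        frames.append(img.pixels)
        truth.append((x / ps, y / ps))
        heading += rng.normal(0.0, 0.25)
        nx = x + speed_um_per_frame * math.cos(heading)
        ny = y + speed_um_per_frame * math.sin(heading)
        if not margin < nx < frame_um - margin:
            heading = math.pi - heading
            nx = x + speed_um_per_frame * math.cos(heading)
        if not margin < ny < frame_um - margin:
            heading = -heading
            ny = y + speed_um_per_frame * math.sin(heading)
        x, y = float(np.clip(nx, margin, frame_um - margin)), float(
            np.clip(ny, margin, frame_um - margin)
        )
        intensity *= fade_per_frame
        width += width_growth_um_per_frame
        angle += angle_drift_deg_per_frame
    return frames, truth
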