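"""Closed-loop virtual cell sorting.

Orchestrates the full aspirate-and-place loop against the virtual
microscope: rough locating of red targets, depth estimation and refocus,
precise locating (with watershed separation when boxes overlap), pipette
approach under template tracking, and aspiration within a capture radius.
Fields of view are visited in a serpentine raster until enough cells are
collected.  All physics is reduced to geometry — aspiration succeeds when
the tracked tip is within the capture radius of a cell — so the reported
purity and recovery measure the vision-and-control chain, not fluidics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import depth_mdfd, instance_segmentation, planar_locating, tracking
from .errors import InvalidParameterError
from .imaging_model import (
    CellSpec,
    FluorescenceImage,
    OpticsConfig,
    PipetteSpec,
    Scene,
    render_scene,
)

__all__ = ["SortConfig", "VirtualRig", "SortReport", "sort_fov", "scan_dish", "compute_metrics"]


@dataclass
class SortConfig:
    capture_radius_um: float = 9.5
    max_pipette_step_um: float = 5.0
    mis_capture_prob: float = 0.0
    accept_threshold: float = 0.6
    step_um: float = 6.0
    template_size_px: int = 41
    center_tol_px: float = 5.0
    fov_overlap: float = 0.1
    focused_diameter: float = 16.0
    max_targets_per_fov: int = 50


@dataclass
class SortReport:
    fovs: list[dict] = field(default_factory=list)
    aspirated_ids: list[int] = field(default_factory=list)
    aspirated_colors: list[str] = field(default_factory=list)
    out_of_range_ids: list[int] = field(default_factory=list)
    steps: int = 0
    purity: float = float("nan")
    recovery: float = float("nan")
    cells_per_step: float = float("nan")


@dataclass
class VirtualRig:
    """Stand-in for stage, camera and pump: holds the world state and
    renders what the camera would see."""

    scene: Scene
    optics: OpticsConfig
    fov_size: tuple[float, float] = (200.0, 200.0)
    fov_origin: tuple[float, float] = (0.0, 0.0)
    focal_z: float = 0.0
    pipette: PipetteSpec = field(
        default_factory=lambda: PipetteSpec(tip_x=20.0, tip_y=20.0, tip_z=0.0)
    )
    aspirated_ids: list[int] = field(default_factory=list)
    _frame_counter: int = 0

    def visible_cells(self, margin: float = 20.0) -> list[CellSpec]:
        ox, oy = self.fov_origin
        w, h = self.fov_size
        return [
            c
            for c in self.scene.cells
            if c.id not in self.aspirated_ids
            and -margin <= c.x - ox <= w + margin
            and -margin <= c.y - oy <= h + margin
        ]

    def render(self, *, with_pipette: bool = True) -> FluorescenceImage:
        ox, oy = self.fov_origin
        cells = [
            replace(c, x=c.x - ox, y=c.y - oy) for c in self.visible_cells()
        ]
        pip = None
        if with_pipette:
            pip = replace(
                self.pipette, tip_x=self.pipette.tip_x - ox, tip_y=self.pipette.tip_y - oy
            )
        self._frame_counter += 1
        local = Scene(
            cells=cells,
            fov_width=self.fov_size[0],
            fov_height=self.fov_size[1],
            pipette=pip,
            rng_seed=self.scene.rng_seed + self._frame_counter,
        )
        return render_scene(local, self.focal_z, self.optics)

    def aspirate(self, cell_id: int) -> None:
        if cell_id in self.aspirated_ids:
            raise InvalidParameterError(f"cell {cell_id} already aspirated")
        self.aspirated_ids.append(cell_id)


def _nearest_cell(
    rig: VirtualRig, x_um: float, y_um: float, radius_um: float
) -> CellSpec | None:
    best = None
    best_d = radius_um
    for c in rig.visible_cells(margin=0.0):
        dist = math.hypot(c.x - x_um, c.y - y_um)
        if dist <= best_d:
            best, best_d = c, dist
    return best


def sort_fov(rig: VirtualRig, config: SortConfig | None = None,
             rng: np.random.Generator | None = None,
             max_aspirations: int | None = None) -> dict:
    """Detect, focus, locate, track and aspirate every red target in the
    current field of view (or until ``max_aspirations`` cells have been
    collected).  Returns a per-FOV record (detections, depth estimates,
    aspirations, simulation steps)."""
    cfg = config or SortConfig()
    rng = rng or np.random.default_rng(rig.scene.rng_seed)
    optics = rig.optics
    ps = optics.pixel_size
    ox, oy = rig.fov_origin
    reference = planar_locating.make_reference_template(optics, cfg.focused_diameter)
    pyramid = planar_locating.build_scalable_templates(reference)
    record: dict = {
        "origin": rig.fov_origin, "detections": [], "depths": [],
        "aspirated": [], "out_of_range": [], "steps": 0,
    }
    skip_centers: list[tuple[float, float]] = []

    for _round in range(cfg.max_targets_per_fov):
        if max_aspirations is not None and len(record["aspirated"]) >= max_aspirations:
            break
        img = rig.render(with_pipette=False)
        red = img.channel("red")
        dets, rois = planar_locating.rough_locate(red, pyramid, cfg.accept_threshold)
        dets_rois = [
            (det, roi)
            for det, roi in zip(dets, rois)
            if not any(
                math.hypot(det.center_x - sx, det.center_y - sy) <= cfg.center_tol_px
                for sx, sy in skip_centers
            )
        ]
        if not dets_rois:
            break
        det, roi = dets_rois[0]
        record["detections"].append(det)

        # --- depth detection inside the ROI, then refocus
        base_z = rig.focal_z

        def provider(z: float) -> np.ndarray:
            rig.focal_z = base_z + z
            frame = rig.render(with_pipette=False).channel("red")
            x, y, w, h = roi.bbox
            return frame[y : y + h, x : x + w]

        est = depth_mdfd.mdfd_estimate(
            provider, d=cfg.step_um,
            config=depth_mdfd.MdfdConfig(valid_depth_range=optics.valid_depth_range),
        )
        rig.focal_z = base_z
        record["depths"].append(est)
        record["steps"] += est.iterations * 3
        if est.status == "out_of_range":
            skip_centers.append((det.center_x, det.center_y))
            truth = _nearest_cell(rig, ox + det.center_x * ps, oy + det.center_y * ps, 30.0)
            if truth is not None:
                record["out_of_range"].append(truth.id)
            continue
        rig.focal_z = base_z + est.d_n

        # --- precise locating at the focused plane
        img2 = rig.render(with_pipette=False)
        red2 = img2.channel("red")
        pdets = planar_locating.precise_locate(red2, reference, cfg.accept_threshold)
        if not pdets:
            skip_centers.append((det.center_x, det.center_y))
            rig.focal_z = base_z
            continue
        target = min(
            pdets, key=lambda p: math.hypot(p.center_x - det.center_x, p.center_y - det.center_y)
        )
        groups = instance_segmentation.overlap_judgement(pdets)
        group = next(g for g in groups if pdets.index(target) in g)
        tx_px, ty_px = target.center_x, target.center_y
        if len(group) >= 2:
            seg = instance_segmentation.segment_overlapped(img2.pixels, pdets, group)
            if seg.centers:
                tx_px, ty_px = min(
                    seg.centers,
                    key=lambda c: math.hypot(c[0] - target.center_x, c[1] - target.center_y),
                )
        target_um = (ox + tx_px * ps, oy + ty_px * ps)

        # --- pipette approach under tracking
        dz = abs(rig.focal_z - rig.pipette.tip_z)
        record["steps"] += int(math.ceil(dz / cfg.max_pipette_step_um))
        rig.pipette = replace(rig.pipette, tip_z=rig.focal_z)
        frame = rig.render(with_pipette=True).channel("red")
        tip_px = ((rig.pipette.tip_x - ox) / ps, (rig.pipette.tip_y - oy) / ps)
        try:
            state = tracking.init_track(frame, tip_px, cfg.template_size_px)
        except InvalidParameterError:
            state = None
        tracked_um = (rig.pipette.tip_x, rig.pipette.tip_y)
        for _step in range(400):
            dx = target_um[0] - rig.pipette.tip_x
            dy = target_um[1] - rig.pipette.tip_y
            dist = math.hypot(dx, dy)
            if dist <= cfg.capture_radius_um:
                break
            scale = min(1.0, cfg.max_pipette_step_um / dist)
            rig.pipette = replace(
                rig.pipette,
                tip_x=rig.pipette.tip_x + dx * scale,
                tip_y=rig.pipette.tip_y + dy * scale,
            )
            record["steps"] += 1
            frame = rig.render(with_pipette=True).channel("red")
            if state is not None:
                state = tracking.track_step(frame, state)
                if state.lost:  # re-initialise from the known pose
                    tip_px = ((rig.pipette.tip_x - ox) / ps, (rig.pipette.tip_y - oy) / ps)
                    try:
                        state = tracking.init_track(frame, tip_px, cfg.template_size_px)
                    except InvalidParameterError:
                        state = None
            if state is not None:
                bx, by, bw, bh = state.last_bbox
                tracked_um = (
                    ox + (bx + (bw - 1) / 2.0) * ps,
                    oy + (by + (bh - 1) / 2.0) * ps,
                )
            else:
                tracked_um = (rig.pipette.tip_x, rig.pipette.tip_y)

        # --- aspirate whatever sits under the tracked tip
        captured = _nearest_cell(rig, tracked_um[0], tracked_um[1], cfg.capture_radius_um)
        if captured is None:
            skip_centers.append((det.center_x, det.center_y))
            rig.focal_z = base_z
            continue
        if cfg.mis_capture_prob > 0 and rng.uniform() < cfg.mis_capture_prob:
            neighbours = [
                c for c in rig.visible_cells(margin=0.0) if c.id != captured.id
            ]
            if neighbours:
                captured = min(
                    neighbours,
                    key=lambda c: math.hypot(c.x - tracked_um[0], c.y - tracked_um[1]),
                )
        rig.aspirate(captured.id)
        record["aspirated"].append((captured.id, captured.color))
        record["steps"] += 1
        rig.focal_z = base_z
    return record


def scan_dish(
    rig: VirtualRig,
    dish_diameter_mm: float = 35.0,
    stop_count: int = 1,
    config: SortConfig | None = None,
) -> SortReport:
    """Serpentine raster of fields of view over the dish (bounded by the
    scene extent), sorting each FOV until ``stop_count`` cells are
    collected or the dish is exhausted."""
    if stop_count < 1:
        raise InvalidParameterError("stop_count must be >= 1")
    cfg = config or SortConfig()
    rng = np.random.default_rng(rig.scene.rng_seed)
    report = SortReport()
    fw, fh = rig.fov_size
    step_x = fw * (1.0 - cfg.fov_overlap)
    step_y = fh * (1.0 - cfg.fov_overlap)
    dish_um = dish_diameter_mm * 1000.0
    extent_x = min(rig.scene.fov_width, dish_um)
    extent_y = min(rig.scene.fov_height, dish_um)
    nx = max(1, int(math.ceil((extent_x - fw) / step_x)) + 1)
    ny = max(1, int(math.ceil((extent_y - fh) / step_y)) + 1)

    done = False
    for iy in range(ny):
        cols = range(nx) if iy % 2 == 0 else range(nx - 1, -1, -1)
        for ix in cols:
            rig.fov_origin = (
                min(ix * step_x, max(0.0, extent_x - fw)),
                min(iy * step_y, max(0.0, extent_y - fh)),
            )
            remaining = stop_count - len(report.aspirated_ids)
            record = sort_fov(rig, cfg, rng, max_aspirations=remaining)
            report.fovs.append(record)
            report.steps += record["steps"] + 1  # +1 for the FOV move
            for cid, color in record["aspirated"]:
                report.aspirated_ids.append(cid)
                report.aspirated_colors.append(color)
            report.out_of_range_ids.extend(record["out_of_range"])
            if len(report.aspirated_ids) >= stop_count:
                done = True
                break
        if done:
            break
    return compute_metrics(report, rig.scene)


def compute_metrics(report: SortReport, scene_truth: Scene) -> SortReport:
    """Purity (targets among aspirated), recovery (targets collected over
    targets present) and speed in cells per simulation step."""
    target_ids = {c.id for c in scene_truth.cells if c.color == "red"}
    aspirated = set(report.aspirated_ids)
    true_hits = len(aspirated & target_ids)
    report.purity = true_hits / len(aspirated) if aspirated else float("nan")
    report.recovery = true_hits / len(target_ids) if target_ids else float("nan")
    report.cells_per_step = (
        len(aspirated) / report.steps if report.steps > 0 else float("nan")
    )
    return report
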