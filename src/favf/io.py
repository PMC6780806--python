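"""Reading and writing the package's on-disk formats: TIFF images, JSON
scene ground truth, YAML optics configuration, CSV detections/tracks."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging_model import CellSpec, FluorescenceImage, OpticsConfig, PipetteSpec, Scene
from .planar_locating import Detection

__all__ = [
    "write_image",
    "read_image",
    "write_stack",
    "read_stack",
    "scene_to_json",
    "scene_from_json",
    "optics_to_yaml",
    "optics_from_yaml",
    "detections_to_csv",
    "detections_from_csv",
]


def write_image(path: str | Path, image: FluorescenceImage | np.ndarray,
                *, dtype: str = "uint16") -> None:
    arr = image.pixels if isinstance(image, FluorescenceImage) else np.asarray(image)
    if dtype == "uint8":
        out = np.clip(arr, 0, 255).astype(np.uint8)
    elif dtype == "uint16":
        out = np.clip(arr * 257.0, 0, 65535).astype(np.uint16)  # 8-bit range -> 16-bit
    else:
        out = arr.astype(np.float32)
    tifffile.imwrite(str(path), out)


def read_image(path: str | Path, pixel_size: float = 1.0) -> FluorescenceImage:
    arr = tifffile.imread(str(path)).astype(float)
    if arr.dtype != float:
        arr = arr.astype(float)
    if arr.max() > 255.0:
        arr = arr / 257.0
    return FluorescenceImage(pixels=arr, pixel_size=pixel_size, z_plane=0.0)


def write_stack(path: str | Path, images: list[np.ndarray]) -> None:
    arrs = [np.clip(np.asarray(a) * 257.0, 0, 65535).astype(np.uint16) for a in images]
    tifffile.imwrite(str(path), np.stack(arrs), photometric="minisblack")


def read_stack(path: str | Path) -> list[np.ndarray]:
    arr = tifffile.imread(str(path)).astype(float)
    if arr.max() > 255.0:
        arr = arr / 257.0
    return [arr[i] for i in range(arr.shape[0])]


def scene_to_json(scene: Scene, path: str | Path) -> None:
    payload = {
        "fov_width": scene.fov_width,
        "fov_height": scene.fov_height,
        "seed": scene.rng_seed,
        "cells": [
            {"id": c.id, "x": c.x, "y": c.y, "z": c.z, "d": c.focused_diameter,
             "color": c.color, "peak": c.peak_intensity}
            for c in scene.cells
        ],
        "pipette": dataclasses.asdict(scene.pipette) if scene.pipette else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def scene_from_json(path: str | Path) -> Scene:
    payload = json.loads(Path(path).read_text())
    cells = [
        CellSpec(id=c["id"], x=c["x"], y=c["y"], z=c["z"],
                 focused_diameter=c["d"], color=c["color"],
                 peak_intensity=c.get("peak", 180.0))
        for c in payload["cells"]
    ]
    pip = PipetteSpec(**payload["pipette"]) if payload.get("pipette") else None
    return Scene(cells=cells, fov_width=payload["fov_width"],
                 fov_height=payload["fov_height"], pipette=pip,
                 rng_seed=payload.get("seed", 0))


def optics_to_yaml(optics: OpticsConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(optics)))


def optics_from_yaml(path: str | Path) -> OpticsConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return OpticsConfig(**data)


def detections_to_csv(detections: list[Detection], path: str | Path) -> None:
    rows = [
        {"id": i, "stage": d.stage, "x": d.center_x, "y": d.center_y,
         "w": d.bbox[2], "h": d.bbox[3], "score": d.score,
         "scale_index": d.scale_index}
        for i, d in enumerate(detections)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def detections_from_csv(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(
            center_x=row.x, center_y=row.y,
            bbox=(int(round(row.x - (row.w - 1) / 2)), int(round(row.y - (row.h - 1) / 2)),
                  int(row.w), int(row.h)),
            score=row.score, scale_index=int(row.scale_index), stage=row.stage,
        )
        for row in df.itertuples()
    ]
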