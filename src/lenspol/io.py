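"""Stack and map I/O.

Raw capture stacks are stored as multi-page 16-bit grayscale TIFF (one page
per LED, row-major order) with a YAML sidecar describing geometry, mosaic
layout, the intensity scale used for quantization, and seeds.  Recovered
maps are written as 32-bit float TIFF; renders as 8-bit PNG; metric tables
as CSV.
"""

from __future__ import annotations

import csv
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .propagation import SystemGeometry
from .simulate import CaptureStack, MosaicLayout, RawFrame

__all__ = [
    "save_capture_stack",
    "load_capture_stack",
    "save_map_tiff",
    "load_map_tiff",
    "save_png",
    "write_metrics_csv",
    "write_provenance",
]


def _default_config_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def save_capture_stack(stack: CaptureStack, tiff_path: str | Path,
                       config_path: str | Path | None = None,
                       extra: dict | None = None) -> Path:
    """Write a stack as uint16 multi-page TIFF + YAML sidecar; returns the
    sidecar path."""
    tiff_path = Path(tiff_path)
    config_path = Path(config_path) if config_path else _default_config_path(tiff_path)
    data = stack.as_array()
    peak = float(data.max()) or 1.0
    scale = 65535.0 / peak
    quantized = np.round(data * scale).astype(np.uint16)
    tifffile.imwrite(tiff_path, quantized, photometric="minisblack")
    config = {
        "geometry": asdict(stack.geometry),
        "layout": [list(row) for row in stack.layout.angles_deg],
        "led_indices": [list(i) for i in stack.led_indices],
        "intensity_scale": scale,
        "n_frames": len(stack),
    }
    if extra:
        config.update(extra)
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path


def _geometry_from_config(cfg: dict) -> SystemGeometry:
    g = dict(cfg["geometry"])
    for key in ("led_grid", "sensor_px"):
        g[key] = tuple(g[key])
    return SystemGeometry(**g)


def load_capture_stack(tiff_path: str | Path,
                       config_path: str | Path | None = None) -> CaptureStack:
    tiff_path = Path(tiff_path)
    config_path = Path(config_path) if config_path else _default_config_path(tiff_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    geometry = _geometry_from_config(cfg)
    layout = MosaicLayout(tuple(tuple(float(a) for a in row) for row in cfg["layout"]))
    data = tifffile.imread(tiff_path).astype(float) / float(cfg["intensity_scale"])
    if data.ndim == 2:
        data = data[None]
    led_indices = [tuple(i) for i in cfg["led_indices"]]
    frames = [RawFrame(values=frame, led_index=idx, layout=layout)
              for frame, idx in zip(data, led_indices)]
    return CaptureStack(frames=frames, geometry=geometry, layout=layout)


def save_map_tiff(path: str | Path, values: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def load_map_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def save_png(path: str | Path, rgb: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).astype(np.uint8))


def write_metrics_csv(path: str | Path, rows: dict[str, float]) -> None:
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "value"])
        for name, value in rows.items():
            writer.writerow([name, value])


def write_provenance(path: str | Path, info: dict) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return _clean(asdict(obj))
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(Path(path), "w") as fh:
        yaml.safe_dump(_clean(info), fh, sort_keys=False)
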