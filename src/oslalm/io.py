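"""Disk containers: raw float64 + JSON sidecar, and windowed 16-bit PNG.

The raw container is a headerless little-endian float64 binary (row-major;
sinograms view-major) next to a ``<stem>.json`` sidecar holding the shape
and geometry fields, so any tool that can read flat binaries can consume
the data without this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .geometry import Image, ScanGeometry, Sinogram

__all__ = [
    "save_raw",
    "load_raw",
    "save_sinogram",
    "load_sinogram",
    "save_image",
    "load_image",
    "save_png16",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_raw(path, array: np.ndarray, header: dict) -> None:
    path = Path(path)
    arr = np.ascontiguousarray(np.asarray(array, dtype="<f8"))
    path.write_bytes(arr.tobytes())
    meta = {"dtype": "<f8", "shape": list(arr.shape), **header}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_raw(path):
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    arr = np.frombuffer(path.read_bytes(), dtype=meta["dtype"]).reshape(meta["shape"])
    return arr.copy(), meta


def save_sinogram(path, sino: Sinogram) -> None:
    g = sino.geometry
    save_raw(
        path,
        sino.values,
        {
            "kind": "sinogram",
            "n_views": g.n_views,
            "n_bins": g.n_bins,
            "bin_spacing": g.bin_spacing,
            "detector_offset": g.detector_offset,
            "view_angles": list(g.view_angles),
            "n_x": g.n_x,
            "n_y": g.n_y,
            "pixel_size": g.pixel_size,
        },
    )


def load_sinogram(path) -> Sinogram:
    arr, meta = load_raw(path)
    geom = ScanGeometry(
        n_x=meta["n_x"],
        n_y=meta["n_y"],
        pixel_size=meta["pixel_size"],
        view_angles=tuple(meta["view_angles"]),
        n_bins=meta["n_bins"],
        bin_spacing=meta["bin_spacing"],
        detector_offset=meta.get("detector_offset", 0.0),
    )
    return Sinogram(arr, geom)


def save_image(path, image: Image) -> None:
    save_raw(path, image.values, {"kind": "image", "pixel_size": image.pixel_size})


def load_image(path) -> Image:
    arr, meta = load_raw(path)
    return Image(arr, meta.get("pixel_size", 1.0))


def save_png16(path, image, window=None) -> None:
    """Write a windowed 16-bit grayscale PNG preview.

    ``window = (lo, hi)`` maps attenuation values to [0, 65535]; default is
    the image's own range.
    """
    vals = image.values if isinstance(image, Image) else np.asarray(image, dtype=float)
    lo, hi = window if window is not None else (vals.min(), vals.max())
    if hi <= lo:
        hi = lo + 1.0
    scaled = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    data = (scaled * 65535).astype(np.uint16)
    PILImage.fromarray(data).save(Path(path))
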