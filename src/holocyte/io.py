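"""Reading and writing frames, sidecars, configs and detection tables.

Holograms and reconstructed amplitudes travel as single-channel TIFF
(16-bit by default) or PNG (8-bit); integer images are divided by their
dtype maximum on load so every threshold in the package operates on the
[0, 1] scale.  Each written frame gets a JSON sidecar carrying the
optics parameters, sensor model, seed and ground-truth cells, which is
what makes simulated datasets self-describing and reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .cytometry import CellDetection, ChannelGeometry
from .optics import OpticsParams
from .simulate import Hologram, Phantom, SensorModel

__all__ = [
    "write_image",
    "read_image",
    "write_hologram",
    "read_hologram",
    "write_sidecar",
    "read_sidecar",
    "load_run_config",
    "write_detections_csv",
    "write_rmse_csv",
]


def write_image(path: str | Path, image: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0, 1] float image as 8- or 16-bit grayscale TIFF/PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 16:
        data = np.round(arr * 65535).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(arr * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        Image.fromarray(data).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image and normalise by its dtype maximum."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.asarray(Image.open(path))
    if data.ndim != 2:
        raise ValueError(f"expected single-channel image, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.float64) / np.iinfo(data.dtype).max
    return data.astype(np.float64)


def _optics_dict(params: OpticsParams) -> dict:
    d = asdict(params)
    d["grid_shape"] = list(params.grid_shape)
    return d


def _optics_from_dict(d: dict) -> OpticsParams:
    return OpticsParams(
        wavelength=float(d["wavelength"]),
        distance_d=float(d["distance_d"]),
        pixel_pitch=float(d["pixel_pitch"]),
        grid_shape=tuple(int(x) for x in d["grid_shape"]),
        source_distance_d1=d.get("source_distance_d1"),
    )


def write_sidecar(
    path: str | Path,
    params: OpticsParams,
    sensor: SensorModel | None = None,
    seed: int | None = None,
    phantom: Phantom | None = None,
    extra: dict | None = None,
) -> None:
    """Write the JSON sidecar describing a frame."""
    payload: dict = {"optics": _optics_dict(params)}
    if sensor is not None:
        payload["sensor"] = asdict(sensor)
    if seed is not None:
        payload["seed"] = int(seed)
    if phantom is not None:
        payload["truth_cells"] = [
            {
                "center_row": r,
                "center_col": c,
                "radius_px": rad,
                "peak_opacity": op,
            }
            for (r, c, rad, op) in phantom.truth_cells
        ]
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["optics"] = _optics_from_dict(payload["optics"])
    if "sensor" in payload:
        payload["sensor"] = SensorModel(**payload["sensor"])
    return payload


def write_hologram(
    path: str | Path,
    holo: Hologram,
    sensor: SensorModel | None = None,
    seed: int | None = None,
    phantom: Phantom | None = None,
) -> None:
    """Write a hologram frame plus its JSON sidecar."""
    bit_depth = sensor.bit_depth if sensor is not None else 16
    write_image(path, holo.intensity, bit_depth=16 if bit_depth > 8 else 8)
    sidecar = Path(path).with_suffix(".json")
    write_sidecar(
        sidecar,
        holo.params,
        sensor=sensor,
        seed=seed,
        phantom=phantom,
        extra={
            "frame_id": holo.frame_id,
            "is_background": holo.is_background,
            "exposure_phase": holo.exposure_phase,
        },
    )


def read_hologram(path: str | Path) -> Hologram:
    """Read a frame written by :func:`write_hologram` (sidecar required)."""
    sidecar = read_sidecar(Path(path).with_suffix(".json"))
    intensity = read_image(path)
    return Hologram(
        intensity=intensity,
        params=sidecar["optics"],
        is_background=bool(sidecar.get("is_background", False)),
        frame_id=str(sidecar.get("frame_id", "")),
        exposure_phase=str(sidecar.get("exposure_phase", "static")),
    )


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration.

    Recognised sections mirror the dataclass fields: ``optics``,
    ``sensor``, ``recon`` (n_iterations, threshold, variant, ...),
    ``geometry`` (height_um, width_um, length_mm), plus scalar
    ``dilution`` and ``seed``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    if "optics" in raw:
        out["optics"] = _optics_from_dict(raw["optics"])
    if "sensor" in raw:
        out["sensor"] = SensorModel(**raw["sensor"])
    if "geometry" in raw:
        out["geometry"] = ChannelGeometry(**raw["geometry"])
    if "recon" in raw:
        out["recon"] = dict(raw["recon"])
    for key in ("dilution", "seed", "n_cells", "n_frames"):
        if key in raw:
            out[key] = raw[key]
    return out


def write_detections_csv(path: str | Path, detections: list[CellDetection]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["frame_id", "row", "col", "area_px", "diameter_um", "mean_depth"]
        )
        for d in detections:
            writer.writerow(
                [
                    d.frame_id,
                    f"{d.centroid[0]:.2f}",
                    f"{d.centroid[1]:.2f}",
                    d.area_px,
                    f"{d.equivalent_diameter_um:.2f}",
                    f"{d.mean_depth:.4f}",
                ]
            )


def write_rmse_csv(
    path: str | Path,
    per_iteration_rmse: list[float],
    header: dict | None = None,
) -> None:
    """Per-iteration RMSE log; optional header metadata as comments."""
    with open(path, "w", newline="") as fh:
        if header:
            for k, v in header.items():
                fh.write(f"# {k}: {v}\n")
        writer = csv.writer(fh)
        writer.writerow(["iteration", "rmse"])
        for i, r in enumerate(per_iteration_rmse, start=1):
            writer.writerow([i, f"{r:.8f}"])
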