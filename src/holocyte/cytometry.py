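"""From reconstructed frames to cell counts and concentrations.

The counting chain mirrors a classic counting chamber read out by
software: flat-field the reconstructed amplitude against a cell-free
background, threshold-segment the dark cell cores, count connected
components, and convert the count to a concentration using the known
micro-channel volume and the sample dilution.  A frame-to-frame RMSE
test gates counting to frames in which the fluid is stationary, which
is how pulse-injection (flow / stop cycles) is supervised when the
channel is driven by hand instead of a micro-pump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .reconstruct import ReconConfig, reconstruct, rmse
from .simulate import Hologram

__all__ = [
    "ChannelGeometry",
    "CellDetection",
    "CountResult",
    "remove_background",
    "segment_cells",
    "channel_volume_uL",
    "channel_area_mm2",
    "sensor_area_mm2",
    "concentration_per_L",
    "detect_motion",
    "calibrate_motion_threshold",
    "compare_counts",
    "count_frame",
    "count_frames",
]

# Segmentation defaults for counting on background-removed amplitude
# images (background ~ 1.0, cell cores dark).  A single-shot in-line
# reconstruction splits object contrast evenly with the twin ghost, so
# the shallowest countable cell (half-transparent) dips only ~0.2 below
# background while residual ghost ripple stays within ~0.1 of it; the
# cutoff sits between those.  min_area rejects single-pixel noise,
# max_area rejects debris and unresolved clumps far larger than a
# single leukocyte.
DEFAULT_COUNT_THRESHOLD = 0.82
DEFAULT_MIN_AREA_PX = 2
DEFAULT_MAX_AREA_PX = 400


@dataclass(frozen=True)
class ChannelGeometry:
    """Micro-channel dimensions: height and width in micrometres, length
    in millimetres (the S-shaped channel unrolled)."""

    height_um: float = 30.0
    width_um: float = 150.0
    length_mm: float = 54.6

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_um <= 0 or self.length_mm < 0:
            raise ValueError("channel dimensions must be positive")


@dataclass
class CellDetection:
    """One segmented cell: centroid in pixels, area in px^2, equivalent
    circular diameter in micrometres, and the mean amplitude deficit
    (1 - corrected amplitude) over its pixels."""

    centroid: tuple[float, float]
    area_px: int
    equivalent_diameter_um: float
    mean_depth: float
    frame_id: str = ""


@dataclass
class CountResult:
    """Aggregated count over one or more frames, with the concentration
    referred back to the undiluted sample."""

    detections: list[CellDetection]
    count: int
    frame_ids: list[str]
    volume_sampled_uL: float
    dilution: float
    concentration_per_L: float


def remove_background(
    recon_amplitude: np.ndarray,
    background_amplitude: np.ndarray,
) -> np.ndarray:
    """Flat-field correction: the ratio image ``recon / background``.

    Divides out any smooth illumination shading so that clear-channel
    pixels sit at 1.0 whatever the lamp profile; clipped to [0, 2].
    """
    recon = np.asarray(recon_amplitude, dtype=np.float64)
    bg = np.asarray(background_amplitude, dtype=np.float64)
    if recon.shape != bg.shape:
        raise ValueError("shape mismatch between frame and background")
    if np.any(bg <= 0):
        raise ValueError("background amplitude must be strictly positive")
    return np.clip(recon / bg, 0.0, 2.0)


def segment_cells(
    corrected: np.ndarray,
    pixel_pitch_m: float,
    threshold: float = DEFAULT_COUNT_THRESHOLD,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
    border_gutter: bool = True,
    frame_id: str = "",
) -> list[CellDetection]:
    """Threshold segmentation of the background-removed amplitude image.

    Cell pixels are those strictly below ``threshold``; connected
    components use 8-connectivity, and components outside
    ``[min_area_px, max_area_px]`` are discarded.  With
    ``border_gutter`` a component whose centroid lies within one
    equivalent radius of the frame edge is dropped, the usual
    counting-chamber rule for objects cut by the field of view.
    """
    corrected = np.asarray(corrected, dtype=np.float64)
    mask = corrected < threshold
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    pitch_um = pixel_pitch_m * 1e6
    rows, cols = corrected.shape
    detections: list[CellDetection] = []
    for region in measure.regionprops(labels):
        area = int(region.area)
        if area < min_area_px or area > max_area_px:
            continue
        r0, c0 = region.centroid
        eq_radius_px = float(np.sqrt(area / np.pi))
        if border_gutter and (
            r0 < eq_radius_px
            or c0 < eq_radius_px
            or r0 > rows - 1 - eq_radius_px
            or c0 > cols - 1 - eq_radius_px
        ):
            continue
        region_mask = labels == region.label
        depth = float(np.mean(1.0 - corrected[region_mask]))
        detections.append(
            CellDetection(
                centroid=(float(r0), float(c0)),
                area_px=area,
                equivalent_diameter_um=2.0 * eq_radius_px * pitch_um,
                mean_depth=depth,
                frame_id=frame_id,
            )
        )
    return detections


def channel_volume_uL(geom: ChannelGeometry) -> float:
    """Channel volume height x width x length, in microlitres."""
    volume_um3 = geom.height_um * geom.width_um * geom.length_mm * 1e3
    return volume_um3 * 1e-9  # 1 uL = 1 mm^3 = 1e9 um^3


def channel_area_mm2(geom: ChannelGeometry) -> float:
    """Projective (footprint) area width x length, in mm^2."""
    return geom.width_um * 1e-3 * geom.length_mm


def sensor_area_mm2(n_rows: int, n_cols: int, pixel_pitch_m: float) -> float:
    """Active sensor area of an ``n_rows x n_cols`` array, in mm^2."""
    pitch_mm = pixel_pitch_m * 1e3
    return n_rows * pitch_mm * n_cols * pitch_mm


def concentration_per_L(
    count: int,
    geom: ChannelGeometry,
    dilution: float = 1.0,
    n_frames: int = 1,
    frame_fraction: float = 1.0,
) -> float:
    """Concentration of the undiluted sample, in cells per litre.

    ``frame_fraction`` is the fraction of the channel volume imaged per
    frame; the sensor's field of view exceeds the channel footprint, so
    a full frame sees the whole channel and the default is 1.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if dilution < 1:
        raise ValueError("dilution ratio must be >= 1")
    if not (0.0 < frame_fraction <= 1.0):
        raise ValueError("frame_fraction must lie in (0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    volume_uL = channel_volume_uL(geom) * frame_fraction * n_frames
    if volume_uL == 0:
        raise ValueError("sampled volume is zero")
    volume_L = volume_uL * 1e-6
    return count / volume_L * dilution


def detect_motion(
    frame_a: Hologram,
    frame_b: Hologram,
    motion_threshold: float,
) -> str:
    """Classify the fluid state between two frames: ``"moving"`` iff
    their intensity RMSE exceeds the threshold, else ``"static"``."""
    value = rmse(frame_a.intensity, frame_b.intensity)
    return "moving" if value > motion_threshold else "static"


def calibrate_motion_threshold(
    static_frames: list[Hologram],
    safety_factor: float = 3.0,
) -> float:
    """Motion-detection threshold from repeated exposures of a static
    scene: ``safety_factor`` times the largest pairwise noise-floor RMSE."""
    if len(static_frames) < 2:
        raise ValueError("need at least two repeated static frames")
    floor = max(
        rmse(a.intensity, b.intensity)
        for i, a in enumerate(static_frames)
        for b in static_frames[i + 1 :]
    )
    return safety_factor * floor


def compare_counts(ours: float, reference: float) -> float:
    """Fractional counting error against a reference instrument, in
    percent: ``100 |ours - reference| / reference``, reported to one
    decimal place."""
    if reference <= 0:
        raise ValueError("reference concentration must be positive")
    return round(100.0 * abs(ours - reference) / reference, 1)


def count_frames(
    frames: list[Hologram],
    background: Hologram,
    recon_cfg: ReconConfig,
    geom: ChannelGeometry,
    dilution: float = 1.0,
    threshold: float = DEFAULT_COUNT_THRESHOLD,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
    frame_fraction: float = 1.0,
) -> CountResult:
    """Full counting chain over one or more hologram frames.

    Each frame and the cell-free background are reconstructed with the
    same settings; the frame amplitude is flat-fielded against the
    background amplitude and segmented.  Every frame images a fresh
    channel volume (pulse injection replaces all cells between
    exposures), so counts accumulate over ``len(frames)`` channel
    volumes.
    """
    if not frames:
        raise ValueError("need at least one frame")
    bg_amplitude = reconstruct(background, background, recon_cfg).amplitude_image
    detections: list[CellDetection] = []
    frame_ids: list[str] = []
    for holo in frames:
        res = reconstruct(holo, background, recon_cfg)
        corrected = remove_background(res.amplitude_image, bg_amplitude)
        detections.extend(
            segment_cells(
                corrected,
                recon_cfg.optics.pixel_pitch,
                threshold=threshold,
                min_area_px=min_area_px,
                max_area_px=max_area_px,
                frame_id=holo.frame_id,
            )
        )
        frame_ids.append(holo.frame_id)
    count = len(detections)
    n_frames = len(frames)
    conc = concentration_per_L(
        count, geom, dilution=dilution, n_frames=n_frames,
        frame_fraction=frame_fraction,
    )
    return CountResult(
        detections=detections,
        count=count,
        frame_ids=frame_ids,
        volume_sampled_uL=channel_volume_uL(geom) * frame_fraction * n_frames,
        dilution=dilution,
        concentration_per_L=conc,
    )


def count_frame(
    corrected: np.ndarray,
    pixel_pitch_m: float,
    geom: ChannelGeometry,
    dilution: float = 1.0,
    threshold: float = DEFAULT_COUNT_THRESHOLD,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
    frame_fraction: float = 1.0,
    frame_id: str = "",
) -> CountResult:
    """Segment one background-removed frame and report its count and the
    implied sample concentration."""
    detections = segment_cells(
        corrected,
        pixel_pitch_m,
        threshold=threshold,
        min_area_px=min_area_px,
        max_area_px=max_area_px,
        frame_id=frame_id,
    )
    count = len(detections)
    conc = concentration_per_L(
        count, geom, dilution=dilution, n_frames=1, frame_fraction=frame_fraction
    )
    return CountResult(
        detections=detections,
        count=count,
        frame_ids=[frame_id],
        volume_sampled_uL=channel_volume_uL(geom) * frame_fraction,
        dilution=dilution,
        concentration_per_L=conc,
    )
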