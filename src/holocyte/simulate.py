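"""Synthetic phantoms and their degradation into in-line holograms.

The phantom is an object-plane transmittance map ``O(x, y)`` in [0, 1]:
smooth-edged discs stand in for blood cells or micro-beads suspended in
the micro-channel.  The wavefront leaving the sample is ``U_d = 1 - O``
(a unit plane wave partially absorbed by the cells), optionally carrying
a weak phase delay proportional to the local opacity, as transmissive
cells do.  Propagating ``U_d`` to the sensor, squaring the amplitude and
applying an affine detector response with quantisation yields the
recorded hologram; the optical phase is discarded, which is what creates
the twin-image problem the reconstruction module must undo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import ComplexField, OpticsParams, propagate

__all__ = [
    "Phantom",
    "SensorModel",
    "Hologram",
    "make_phantom",
    "make_leukocyte_phantom",
    "object_wavefront",
    "forward_hologram",
    "make_background",
    "make_flow_sequence",
]

# Phase delay (radians) a fully opaque-equivalent cell pixel imparts.
# Cells delay as well as absorb light; the delay tracks transmittance,
# which is the amplitude-phase correlation the phase-constrained
# initialisation of the reconstruction exploits.
DEFAULT_PHASE_DELAY = 0.75


@dataclass
class Phantom:
    """Object-plane transmittance map plus ground truth.

    ``transmittance`` is the opacity field O(x, y): 0 where the channel
    is clear, up to ``peak_opacity`` at a cell centre.  ``truth_cells``
    lists ``(center_row, center_col, radius_px, peak_opacity)``.
    """

    transmittance: np.ndarray
    truth_cells: list[tuple[float, float, float, float]]
    params: OpticsParams
    phase_delay: float = DEFAULT_PHASE_DELAY
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transmittance = np.asarray(self.transmittance, dtype=np.float64)
        if self.transmittance.shape != self.params.grid_shape:
            raise ValueError("transmittance shape does not match params.grid_shape")
        if self.transmittance.min() < 0 or self.transmittance.max() > 1:
            raise ValueError("transmittance must lie in [0, 1]")
        rows, cols = self.params.grid_shape
        for r, c, rad, _ in self.truth_cells:
            if not (rad <= r <= rows - 1 - rad and rad <= c <= cols - 1 - rad):
                raise ValueError(f"cell at ({r}, {c}) r={rad} extends outside the grid")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.float64)
            if self.phase.shape != self.params.grid_shape:
                raise ValueError("phase map shape does not match params.grid_shape")

    @property
    def n_cells(self) -> int:
        return len(self.truth_cells)


@dataclass(frozen=True)
class SensorModel:
    """Affine detector response ``I_s = alpha + beta * I_0`` with optional
    zero-mean Gaussian read noise and quantisation to ``bit_depth`` bits.

    ``alpha`` and ``beta`` are fractions of full scale; their exact
    values are immaterial downstream because holograms are renormalised
    on load.
    """

    alpha: float = 0.02
    beta: float = 0.9
    bit_depth: int = 16
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta (gain) must be positive")
        if self.alpha < 0:
            raise ValueError("alpha (offset) must be non-negative")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")


@dataclass
class Hologram:
    """A sensor-plane intensity frame, normalised to [0, 1].

    ``is_background`` marks a cell-free flat-field frame D(x, y).
    """

    intensity: np.ndarray
    params: OpticsParams
    is_background: bool = False
    frame_id: str = ""
    exposure_phase: str = "static"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.shape != self.params.grid_shape:
            raise ValueError("intensity shape does not match params.grid_shape")
        if self.intensity.min() < 0:
            raise ValueError("intensity must be non-negative")


def _disc_profile(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
    peak: float,
    rim_px: float,
) -> np.ndarray:
    """Disc of opacity ``peak`` with a raised-cosine rim of width ``rim_px``."""
    rows, cols = shape
    r0, c0 = center
    lo_r = max(int(np.floor(r0 - radius_px - rim_px - 1)), 0)
    hi_r = min(int(np.ceil(r0 + radius_px + rim_px + 2)), rows)
    lo_c = max(int(np.floor(c0 - radius_px - rim_px - 1)), 0)
    hi_c = min(int(np.ceil(c0 + radius_px + rim_px + 2)), cols)
    rr, cc = np.meshgrid(
        np.arange(lo_r, hi_r), np.arange(lo_c, hi_c), indexing="ij"
    )
    dist = np.hypot(rr - r0, cc - c0)
    core = dist <= radius_px - rim_px
    rim = (dist > radius_px - rim_px) & (dist < radius_px + rim_px)
    patch = np.zeros(dist.shape)
    patch[core] = peak
    patch[rim] = peak * 0.5 * (
        1.0 + np.cos(np.pi * (dist[rim] - (radius_px - rim_px)) / (2.0 * rim_px))
    )
    out = np.zeros(shape)
    out[lo_r:hi_r, lo_c:hi_c] = patch
    return out


def make_phantom(
    params: OpticsParams,
    n_cells: int,
    diameter_range_um: tuple[float, float] = (8.0, 14.0),
    opacity_range: tuple[float, float] = (0.75, 0.95),
    min_separation_um: float | None = None,
    seed: int = 0,
    phase_delay: float = DEFAULT_PHASE_DELAY,
    max_attempts_per_cell: int = 2000,
) -> Phantom:
    """Sample a phantom of ``n_cells`` non-overlapping smooth-edged discs.

    Diameters are drawn uniformly from ``diameter_range_um`` (defaults
    span typical red and white blood cells), peak opacities uniformly
    from ``opacity_range``.  Centres are rejection-sampled so every pair
    is at least ``min_separation_um`` apart (default: four maximum cell
    diameters, the well-separated dilution regime) and every disc plus a
    one-diameter gutter stays inside the frame.  Deterministic for a
    fixed seed: one :class:`numpy.random.Generator` drawn in the order
    centre, diameter, opacity per accepted cell.

    Raises
    ------
    ValueError
        If the requested packing is infeasible after the bounded number
        of rejection-sampling attempts (never a silent shortfall).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    d_lo, d_hi = diameter_range_um
    if not (0 < d_lo <= d_hi):
        raise ValueError("diameter_range_um must be positive and ordered")
    if min_separation_um is None:
        min_separation_um = 4.0 * d_hi
    rng = np.random.default_rng(seed)
    pitch_um = params.pixel_pitch * 1e6
    min_sep_px = min_separation_um / pitch_um
    rows, cols = params.grid_shape
    margin_px = (d_hi / pitch_um) + 2.0  # disc + gutter fully inside frame

    centers: list[tuple[float, float]] = []
    cells: list[tuple[float, float, float, float]] = []
    transmittance = np.zeros(params.grid_shape)
    for k in range(n_cells):
        placed = False
        for _ in range(max_attempts_per_cell):
            r = rng.uniform(margin_px, rows - 1 - margin_px)
            c = rng.uniform(margin_px, cols - 1 - margin_px)
            if all(np.hypot(r - rr, c - cc) >= min_sep_px for rr, cc in centers):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place cell {k + 1}/{n_cells} with min separation "
                f"{min_separation_um} um after {max_attempts_per_cell} attempts"
            )
        diameter_um = rng.uniform(d_lo, d_hi)
        opacity = rng.uniform(*opacity_range)
        radius_px = 0.5 * diameter_um / pitch_um
        rim_px = min(0.75, 0.5 * radius_px)
        disc = _disc_profile(params.grid_shape, (r, c), radius_px, opacity, rim_px)
        transmittance = np.maximum(transmittance, disc)
        centers.append((r, c))
        cells.append((r, c, radius_px, opacity))
    return Phantom(
        transmittance=transmittance,
        truth_cells=cells,
        params=params,
        phase_delay=phase_delay,
    )


def object_wavefront(phantom: Phantom) -> ComplexField:
    """Complex amplitude just downstream of the sample: ``(1 - O)``
    attenuated amplitude carrying the phantom's phase map, or the
    linear delay ``phase_delay * O`` when no explicit map is set."""
    o = phantom.transmittance
    phi = phantom.phase if phantom.phase is not None else phantom.phase_delay * o
    values = (1.0 - o) * np.exp(1j * phi)
    return ComplexField(values=values, params=phantom.params, plane_tag="object")


def make_leukocyte_phantom(
    params: OpticsParams,
    center: tuple[float, float] | None = None,
    body_radius_um: float = 99.0,
    body_opacity: float = 0.75,
) -> Phantom:
    """Single large stained-leucocyte object for convergence studies.

    Emulates a dyed white blood cell as seen through a 20x objective and
    re-sampled on the sensor grid: a sharply bounded absorbing body of
    ~0.2 mm diameter with two darker nucleus lobes.  At these sizes the
    per-object Fresnel number is >> 1 (shadow regime), so the recorded
    intensity deficit tracks the local transmittance - the regime in
    which seeding the initial phase from the intensity deficit is
    physically meaningful.  The phase map is the transmitted-intensity
    deficit ``1 - (1 - O)^2`` itself: absorption and delay both grow
    with the amount of stained cytoplasm traversed.
    """
    rows, cols = params.grid_shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    pitch_um = params.pixel_pitch * 1e6
    r_px = body_radius_um / pitch_um
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    body = np.clip((r_px - np.hypot(rr - center[0], cc - center[1])) / 2.0, 0, 1)
    body = body * body_opacity
    lobe1 = np.clip(
        (0.4 * r_px - np.hypot(rr - center[0] + 8, cc - center[1] - 10)) / 2.0, 0, 1
    ) * 0.2
    lobe2 = np.clip(
        (0.31 * r_px - np.hypot(rr - center[0] - 12, cc - center[1] + 13)) / 2.0, 0, 1
    ) * 0.2
    o = np.clip(body + lobe1 + lobe2, 0.0, 0.95)
    phase = 1.0 - (1.0 - o) ** 2
    return Phantom(
        transmittance=o,
        truth_cells=[(center[0], center[1], r_px, float(o.max()))],
        params=params,
        phase=phase,
    )


def _record(
    intensity_optical: np.ndarray,
    sensor: SensorModel,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Affine response, optional noise, quantisation, renormalise to [0,1]."""
    counts_frac = sensor.alpha + sensor.beta * intensity_optical
    if sensor.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        counts_frac = counts_frac + rng.normal(0.0, sensor.noise_sd, counts_frac.shape)
    full_scale = 2**sensor.bit_depth - 1
    counts = np.clip(np.rint(counts_frac * full_scale), 0, full_scale)
    return counts / full_scale


def forward_hologram(
    phantom: Phantom,
    sensor: SensorModel = SensorModel(),
    *,
    noise_seed: int | None = None,
    frame_id: str = "",
) -> Hologram:
    """Degrade a phantom into the hologram its sensor would record.

    ``U_0 = H_d+[1 - O]``, ``I_0 = |U_0|^2`` (the phase is discarded:
    only intensity reaches the detector), then the affine sensor
    response with quantisation.
    """
    u0 = propagate(object_wavefront(phantom), phantom.params.distance_d)
    i0 = np.abs(u0.values) ** 2
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    return Hologram(
        intensity=_record(i0, sensor, rng),
        params=phantom.params,
        is_background=False,
        frame_id=frame_id,
    )


def make_background(
    params: OpticsParams,
    sensor: SensorModel = SensorModel(),
    shading: np.ndarray | None = None,
    *,
    noise_seed: int | None = None,
    frame_id: str = "background",
) -> Hologram:
    """Cell-free flat-field frame D(x, y): uniform unit intensity or a
    supplied smooth illumination profile, through the same sensor."""
    i0 = np.ones(params.grid_shape) if shading is None else np.asarray(shading, float)
    if i0.shape != params.grid_shape:
        raise ValueError("shading shape does not match params.grid_shape")
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    return Hologram(
        intensity=_record(i0, sensor, rng),
        params=params,
        is_background=True,
        frame_id=frame_id,
    )


def make_flow_sequence(
    phantoms: list[Phantom],
    sensor: SensorModel = SensorModel(),
    *,
    blur_during_flow: bool = False,
    flow_translation_px: int = 20,
    n_blur_samples: int = 8,
    timing: tuple[float, float] = (5.0, 20.0),
) -> list[Hologram]:
    """Emit the frame sequence of pulse-injection operation.

    Each phantom yields one sharp *static* frame (cells stationary
    during the exposure ``t1``); consecutive phantoms carry disjoint
    cells because the channel is flushed between exposures (injection
    time ``t2``).  With ``blur_during_flow`` a motion-blurred *flow*
    frame is inserted after each static frame, formed by averaging the
    holograms of the phantom translated along the channel axis over the
    exposure.  ``timing`` is recorded for bookkeeping only.
    """
    if not phantoms:
        raise ValueError("need at least one phantom")
    del timing  # metadata of the acquisition protocol; no optical effect
    frames: list[Hologram] = []
    for i, ph in enumerate(phantoms):
        frames.append(forward_hologram(ph, sensor, frame_id=f"static_{i:03d}"))
        if blur_during_flow:
            shifts = np.linspace(0, flow_translation_px, max(n_blur_samples, 1))
            acc = np.zeros(ph.params.grid_shape)
            for s in shifts:
                shifted = Phantom(
                    transmittance=_translate(ph.transmittance, s),
                    truth_cells=[],
                    params=ph.params,
                    phase_delay=ph.phase_delay,
                )
                u0 = propagate(
                    object_wavefront(shifted), ph.params.distance_d
                )
                acc += np.abs(u0.values) ** 2
            holo = Hologram(
                intensity=_record(acc / len(shifts), sensor, None),
                params=ph.params,
                frame_id=f"flow_{i:03d}",
                exposure_phase="flow",
            )
            frames.append(holo)
    return frames


def _translate(image: np.ndarray, shift_cols: float) -> np.ndarray:
    """Translate along the channel axis (columns) with wrap-around."""
    n = int(round(shift_cols))
    return np.roll(image, n, axis=1)
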