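"""Scalar-diffraction propagation between object and sensor planes.

The imaging geometry is Gabor in-line holography: a quasi-plane wave
illuminates a weakly scattering sample (the *object plane*) and the
intensity of the diffracted field is recorded a short distance ``d``
downstream on a bare image sensor (the *image plane*).  Free-space
propagation over ``d`` is computed with the angular spectrum method:
the field's 2-D spatial-frequency spectrum is multiplied by the
Rayleigh--Sommerfeld transfer function

    H_d(eps, eta) = exp[ j d (2 pi / lambda) sqrt(1 - (lambda eps)^2
                                                   - (lambda eta)^2) ]

on the propagating band ``eps^2 + eta^2 < 1/lambda^2`` and zero on the
evanescent band.  Positive ``d`` propagates toward the sensor, negative
``d`` back toward the object, and the two are exact inverses on
band-limited fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "OpticsParams",
    "ComplexField",
    "TransferGrid",
    "blue_led_optics",
    "build_transfer",
    "propagate",
    "frequency_grids",
]

PlaneTag = Literal["object", "image"]


@dataclass(frozen=True)
class OpticsParams:
    """Physical parameters of the in-line holographic recording.

    Parameters
    ----------
    wavelength
        Central wavelength of the (quasi-monochromatic) source, in metres.
    distance_d
        Object-plane to image-plane separation, in metres.  The source
        pinhole sits far above the sample (``d1 >> d``), so illumination
        is treated as an on-axis plane wave; ``source_distance_d1`` is
        recorded as metadata only.
    pixel_pitch
        Sensor pixel pitch, in metres.  The object plane is sampled on
        the same grid (unit magnification).
    grid_shape
        ``(rows, cols)`` of the sampled field.
    """

    wavelength: float
    distance_d: float
    pixel_pitch: float
    grid_shape: tuple[int, int]
    source_distance_d1: float | None = None

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if not (self.distance_d > 0):
            raise ValueError(f"distance_d must be positive, got {self.distance_d}")
        if not (self.pixel_pitch > 0):
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ValueError(f"grid_shape must be at least 2x2, got {self.grid_shape}")
        object.__setattr__(self, "grid_shape", (int(rows), int(cols)))

    def with_shape(self, grid_shape: tuple[int, int]) -> "OpticsParams":
        return replace(self, grid_shape=grid_shape)


def blue_led_optics(grid_shape: tuple[int, int] = (512, 512)) -> OpticsParams:
    """Optics of a 465 nm LED + pinhole source over a 2.2 um-pitch sensor
    with the sample plane 0.875 mm above the pixels."""
    return OpticsParams(
        wavelength=465e-9,
        distance_d=0.875e-3,
        pixel_pitch=2.2e-6,
        grid_shape=grid_shape,
        source_distance_d1=5e-2,
    )


@dataclass
class ComplexField:
    """A 2-D complex amplitude sampled on a regular grid.

    ``plane_tag`` records which plane the samples live on; propagation
    flips it.  Entries must be finite.
    """

    values: np.ndarray
    params: OpticsParams
    plane_tag: PlaneTag = "object"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.params.grid_shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match "
                f"params.grid_shape {self.params.grid_shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains NaN or Inf entries")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class TransferGrid:
    """Angular-spectrum transfer function sampled on the DFT frequency grid.

    Unit modulus on the propagating band, exactly zero on the evanescent
    band.  ``distance`` is signed: its sign is the propagation direction
    along the optical axis.
    """

    values: np.ndarray
    params: OpticsParams
    distance: float


def frequency_grids(params: OpticsParams) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency coordinates (cycles per metre) for each DFT bin.

    Standard DFT ordering (DC at index ``[0, 0]``), spacing
    ``1 / (N * pixel_pitch)`` along each axis.
    """
    rows, cols = params.grid_shape
    f_row = np.fft.fftfreq(rows, d=params.pixel_pitch)
    f_col = np.fft.fftfreq(cols, d=params.pixel_pitch)
    return np.meshgrid(f_row, f_col, indexing="ij")


def build_transfer(params: OpticsParams, distance: float) -> TransferGrid:
    """Build the angular-spectrum transfer function for a signed distance.

    ``H(eps, eta) = exp(j * distance * (2 pi / lam) * sqrt(1 - (lam eps)^2
    - (lam eta)^2))`` where ``eps^2 + eta^2 < 1/lam^2``, zero elsewhere
    (hard evanescent cutoff).
    """
    eps, eta = frequency_grids(params)
    lam = params.wavelength
    arg = 1.0 - (lam * eps) ** 2 - (lam * eta) ** 2
    propagating = arg > 0.0
    kz = np.zeros_like(arg)
    np.sqrt(arg, out=kz, where=propagating)
    values = np.where(
        propagating,
        np.exp(1j * distance * (2.0 * np.pi / lam) * kz),
        0.0 + 0.0j,
    )
    return TransferGrid(values=values, params=params, distance=float(distance))


def propagate(
    field: ComplexField,
    distance: float,
    *,
    pad: bool = False,
    transfer: TransferGrid | None = None,
) -> ComplexField:
    """Propagate a field by a signed distance along the optical axis.

    Positive distance moves object -> image (the ``H_d+`` operator),
    negative moves image -> object (``H_d-``); they invert each other on
    band-limited fields.  ``pad=True`` edge-pads to the next power of two
    before transforming to suppress periodic wrap-around for large
    distances (unnecessary at sub-millimetre ``d`` and micron pitch).
    A precomputed ``transfer`` grid may be supplied to amortise kernel
    construction across iterations; it must match the field's params and
    the requested distance.
    """
    params = field.params
    if transfer is not None:
        if transfer.params != params:
            raise ValueError("transfer grid was built for different optics params")
        if transfer.distance != distance:
            raise ValueError(
                f"transfer grid distance {transfer.distance} != requested {distance}"
            )
        if pad:
            raise ValueError("pad is not supported with a precomputed transfer grid")
        out = np.fft.ifft2(transfer.values * np.fft.fft2(field.values))
        new_tag: PlaneTag = "image" if field.plane_tag == "object" else "object"
        return ComplexField(values=out, params=params, plane_tag=new_tag)
    if distance == 0:
        out = field.values.copy()
    elif pad:
        rows, cols = params.grid_shape
        prow = 1 << max(int(np.ceil(np.log2(2 * rows))), 1)
        pcol = 1 << max(int(np.ceil(np.log2(2 * cols))), 1)
        padded = np.pad(
            field.values,
            ((0, prow - rows), (0, pcol - cols)),
            mode="edge",
        )
        big = params.with_shape((prow, pcol))
        h = build_transfer(big, distance)
        out = np.fft.ifft2(h.values * np.fft.fft2(padded))[:rows, :cols]
    else:
        h = build_transfer(params, distance)
        out = np.fft.ifft2(h.values * np.fft.fft2(field.values))
    new_tag: PlaneTag = "image" if field.plane_tag == "object" else "object"
    return ComplexField(values=out, params=params, plane_tag=new_tag)
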