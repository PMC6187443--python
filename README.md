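# holocyte

Lens-free holographic flow cytometry in software: simulate, reconstruct
and count cells imaged by an in-line (Gabor) holographic microscope
built from nothing but an LED, a pinhole, a micro-channel and a bare
CMOS sensor.

In this geometry the cells sit a distance d above the sensor pixels and
the sensor records the interference of the illuminating plane wave with
the light the cells scatter — a hologram, not a focused image. Because
the sensor keeps only intensity, the naive reconstruction (one backward
propagation) is contaminated by the *twin image*, the conjugate of the
object defocused by 2d. This package implements the full computational
chain for such an instrument, for people building or studying low-cost
point-of-care cell counters:

- **optics** — angular-spectrum propagation between the cell plane and
  the sensor plane: `U(z±d) = F⁻¹[H±d · F[U]]` with
  `H_d(ε,η) = exp(i d (2π/λ)√(1−(λε)²−(λη)²))` on the propagating band
  and a hard evanescent cutoff.
- **simulate** — synthetic cell phantoms (opacity discs, 8–14 µm,
  with a weak correlated phase delay) degraded into holograms through
  the forward model and an affine, quantised sensor: `I_s = α + β·|H_d⁺[1−O]|²`.
- **reconstruct** — iterative twin-image suppression alternating an
  object-plane constraint (non-cell pixels blended into the mean-matched
  cell-free background frame) with an image-plane constraint (measured
  amplitude √I_s restored, new phase kept). Two initialisations:
  *classic* (zero phase) and *phase-constrained*, which seeds the phase
  with the intensity deficit, `H_d⁻[√I_s · exp(i(1−I_s))]`, exploiting
  the weak amplitude–phase correlation of transmissive cells; the seeded
  variant converges faster and survives a 20% error in d.
- **cytometry** — flat-field background removal, threshold segmentation
  with 8-connected components, counting-chamber edge rules, channel
  geometry (30 µm × 150 µm × 54.6 mm → 0.246 µL sampled per frame),
  dilution-corrected concentrations in cells/L, frame-to-frame RMSE
  motion gating for pulse-injection operation, and fractional-error
  comparison against a reference counter.
- **cli** — `holocyte simulate | reconstruct | count | evaluate`
  console commands over the library, with TIFF/PNG frames, JSON
  sidecars and YAML configs.

Everything is exercised end-to-end on synthetic phantoms; no external
data is needed.

## Worked example

Simulate one 512×512 frame of 50 cells at the instrument's optics
(465 nm, d = 0.875 mm, 2.2 µm pitch), reconstruct it against a cell-free
background, and count:

```python
from holocyte import (
    ChannelGeometry, ReconConfig, blue_led_optics, count_frames,
    forward_hologram, make_background, make_phantom,
)

optics = blue_led_optics((512, 512))
phantom = make_phantom(optics, n_cells=50, seed=7)
hologram = forward_hologram(phantom, frame_id="frame_000")
background = make_background(optics)

result = count_frames(
    [hologram], background,
    ReconConfig(optics=optics),   # 5 iterations, threshold 0.34, phase-constrained
    ChannelGeometry(),            # 30 um x 150 um x 54.6 mm micro-channel
    dilution=400,
)
```

Output:

```
true cells:    50
counted cells: 50
sampled volume: 0.2457 uL
concentration: 8.140e+10 cells/L
first detection: centroid=(14.2, 103.5) area=28 px^2  diameter=13.1 um
```

All 50 simulated cells are recovered. The concentration refers back to
the undiluted sample: 50 cells in the 0.2457 µL channel fill, times the
1:400 dilution. A real run would aggregate many frames (each frame holds
a fresh channel fill under pulse injection), pushing the counted
population into the thousands.

The same chain is available from the shell:

```
holocyte simulate --out run/ --n-frames 3 --n-cells 50 --seed 7
holocyte reconstruct run/frame_000.tiff run/background.tiff --out run/rec/
holocyte count run/frame_*.tiff --background run/background.tiff \
    --out run/report.json --dilution 400
```

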