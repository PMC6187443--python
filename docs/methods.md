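# Methods

## Imaging model

The instrument modelled here is a lens-free in-line (Gabor) holographic
microscope: a quasi-monochromatic LED (λ = 465 nm) filtered by a pinhole
illuminates cells suspended in a micro-channel that sits directly on a
bare CMOS sensor (pixel pitch 2.2 µm), with the cell plane a distance
d = 0.875 mm above the pixels. Because the pinhole is far away
(d₁ ≈ 5 cm ≫ d), illumination at the sample is treated as an on-axis unit
plane wave. A cell field is described by an opacity map O(x, y) ∈ [0, 1];
the wavefront leaving the sample is

    U_d = (1 − O) · exp(i φ),   φ = weak phase delay correlated with O,

and the sensor records the intensity of the diffracted field,

    I₀ = |H_d⁺[U_d]|²,   I_s = α + β I₀ (+ noise, quantisation),

where H_d± is the angular-spectrum propagator: multiplication of the
field's 2-D spatial-frequency spectrum by
exp(± i d (2π/λ) √(1 − (λε)² − (λη)²)) on the propagating band
ε² + η² < 1/λ², zero on the evanescent band. Forward and backward
propagation are exact inverses on band-limited fields; the implementation
preserves band-limited energy to 1e−9 and matches a brute-force
frequency-domain summation to 1e−8 on a 32×32 grid.

Discretisation follows the standard DFT convention: frequency spacing
1/(N·pitch) per axis, DC at index (0, 0), no implicit padding (an
optional power-of-two edge-pad is available; at d = 0.875 mm and 2.2 µm
pitch wrap-around is negligible for the field sizes used here).

## Twin image and its suppression

The sensor discards phase, so a single back-propagation of the recorded
intensity contains, besides the focused image, its conjugate defocused
by 2d — the twin image. The reconstruction alternates between planes:

1. **Initial estimate.** Back-propagate the measured amplitude √I_s with
   zero phase (classic), or seeded with the intensity-deficit phase
   exp(i(1 − I_s)) (phase-constrained variant). The seed exploits the
   fact that transmissive cells delay light roughly in proportion to how
   strongly they absorb it, so the intensity deficit is a usable proxy
   for the unknown phase.
2. **Cell-region mask.** Threshold the grey-stretched amplitude at 0.34.
   The grey stretch maps the darkest object pixel to 0 and the brightest
   fringe to 1 (extrema taken from a 3×3-median-filtered copy so single
   outlier pixels cannot set the scale); a frame whose total grey range
   is under 15% of its background level is declared cell-free and gets an
   empty mask, so background frames never segment spurious cells.
   Thresholded pixels are consolidated into regions — holes filled,
   support dilated by 2 px — and the support edge is feathered with a
   2-px Gaussian. The dilation stops the constraint from overwriting
   true object pixels; the feathering matters numerically: a hard
   replacement boundary seeds Gibbs-type rings that deepen with every
   propagation round trip (measured ring dips of 0.02 versus 0.89 after
   five iterations on a 50-cell frame, enough to over-segment tenfold).
3. **Object-plane constraint.** Outside the support, blend the field
   into m·D, where D is the measured cell-free background frame (used as
   a zero-phase amplitude) and m = mean|U_r| / mean D matches levels.
4. **Image-plane constraint.** Propagate forward, keep the new phase,
   restore the measured amplitude √I_s, propagate back.

Five iterations are run by default (an optional relative-change
tolerance of 1e−3 can stop earlier); the mask is recomputed each
iteration by default, or frozen after the first estimate
(`freeze_mask`), which is what the convergence studies use — on a single
dense object the support is already well defined at the first estimate,
and freezing removes mask-flicker from the iteration-to-iteration error.

Reconstruction error is tracked as the RMSE between the
background-normalised reconstructed amplitude and the true object
amplitude |1 − O| (background mode mapped to 1.0 via the median, which
is robust because frames are sparse).

## What the convergence study shows

The convergence comparison runs on a dense single-leucocyte phantom
(`make_leukocyte_phantom`): a sharply bounded absorbing body of ~0.2 mm
diameter with two darker nucleus lobes, emulating a stained white cell
imaged through a 20× objective and re-sampled on the sensor grid. At
that size the per-object Fresnel number is ≫ 1 (shadow regime), so the
recorded intensity deficit locally tracks the transmittance and the
phase seed is physically informative. The phantom's phase is the
transmitted-intensity deficit 1 − (1 − O)² itself.

Measured behaviour (512×512, default sensor): the phase-constrained
variant's per-iteration RMSE is at or below the classic variant's at
every iteration, at the calibrated distance and under a 20% distance
mis-calibration, and its final error under mis-calibration is strictly
lower. At the calibrated distance the classic variant's per-iteration
error change falls below 1% by iteration 6; the phase-constrained
variant is still changing ~1.8% there and reaches 1% at iteration 7–8,
so a strict "both variants settle within six iterations" check fails by
one iteration for the seeded variant.

On sparse fields of micron-scale cells (Fresnel number ≪ 1 per cell) the
intensity pattern is dominated by interference rings rather than
shadows, the deficit-phase seed encodes fringe structure rather than
object phase, and the per-iteration dominance does not hold — the seeded
variant starts worse and catches up. Counting accuracy is unaffected
(both variants count exactly; see below).

## Synthetic phantoms

`make_phantom` draws n non-overlapping raised-cosine-rimmed discs:
diameters uniform in 8–14 µm (typical red and white blood cells), peak
opacity uniform in 0.75–0.95 (blood cells absorb strongly at 465 nm —
the haemoglobin Soret band — and stained cells are darker still), phase
delay 0.75 rad × O, centres rejection-sampled with a minimum separation
of four maximum diameters (the dilution regime the instrument operates
in: at 1:400 and beyond, overlap is rare by design) and a one-diameter
gutter to the frame edge. A single integer seed drives one RNG in a
documented draw order (centre, diameter, opacity per accepted cell), so
phantoms are bit-reproducible. Infeasible packings raise after a bounded
number of attempts rather than silently returning fewer cells.

The sensor model is affine (α = 0.02, β = 0.9 of full scale) with
optional Gaussian read noise and quantisation to 16 bits; recorded
frames are renormalised to [0, 1] on load, and the reconstruction is
insensitive to α, β by construction of the grey stretch. Note that β =
0.9 lets strong interference maxima of dense objects clip at full scale,
as they would on a real sensor exposed for the background level.

What the phantoms do **not** model: cell deformation and internal
texture, polychromatic LED spectra and partial coherence, sensor
fixed-pattern noise, hemodynamic flow profiles, and out-of-plane cell
positions (all cells sit exactly in the object plane). Passing the
counting tests therefore demonstrates the correctness of the
reconstruction-and-counting chain under the stated optical model, not
robustness to every nuisance a physical instrument sees.

## Counting and concentration

Counting flat-fields the reconstructed amplitude against the
reconstructed cell-free background (ratio image, clipped to [0, 2]),
thresholds at 0.82, and counts 8-connected components with area in
[2, 400] px², dropping components whose centroid lies within one
equivalent radius of the frame edge (counting-chamber edge rule). The
0.82 cutoff sits between the shallowest countable cell and the residual
ghost ripple: a single-shot in-line reconstruction splits object
contrast evenly with its twin, so a three-quarters-opaque cell dips only
~0.4 below background before iteration, while residual rings stay within
~0.1 of it.

Concentration converts the aggregate count through the channel geometry:
volume = height × width × length (30 µm × 150 µm × 54.6 mm = 0.2457 µL),
each frame images the whole channel (the sensor's 24.4 mm² field of view
covers the 8.19 mm² channel footprint), every frame holds a fresh
channel fill (pulse injection), and the dilution ratio (1:400 for red
cells) is a user input, never recomputed. Frame-to-frame RMSE gates
counting to static frames in hand-driven operation; the motion threshold
is calibrated as 3× the noise-floor RMSE of repeated static exposures.

Measured end-to-end accuracy: for K ∈ {10, 50, 200} cells per 512×512
frame and three seeds each, the counted number equals K in every run
(worst-case relative error 0.0%, bound claimed: ≤ 2%), and a five-point
series spanning an 8× cell-load range fits a line with R² > 0.999.

## Problem sizes and numerical choices

Studies run at 512×512 (the convergence and counting conditions);
property tests use 32–256 px grids. The propagator caches its transfer
grid across iterations. Ties at thresholds resolve to background
(strict inequality for cell membership). The object-plane constraint
scale m uses the mean of amplitudes (a complex mean can vanish).
Degenerate inputs — empty phantoms, all-background masks, cell-free
frames — are all defined and tested rather than special-cased away.
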