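"""Built-in studies: the computations behind the headline numbers.

These functions regenerate their inputs from the synthetic-phantom
module and run the full method, so every number they return is computed
at call time.  ``counting_error_study`` is the headline: worst-case
relative cell-counting error of the complete simulate -> reconstruct ->
segment -> count chain over three frame populations and three seeds.
"""

from __future__ import annotations

import numpy as np

from .cytometry import (
    ChannelGeometry,
    channel_area_mm2,
    channel_volume_uL,
    compare_counts,
    count_frames,
    sensor_area_mm2,
)
from .optics import blue_led_optics
from .reconstruct import ReconConfig, reconstruct
from .simulate import forward_hologram, make_background, make_leukocyte_phantom, make_phantom

__all__ = [
    "counting_error_study",
    "convergence_study",
    "dilution_linearity_study",
    "geometry_numbers",
    "instrument_comparison",
    "run_all",
    "TABLE1_WBC",
    "TABLE1_RBC",
]

# Reference-instrument comparison pairs (ours, hematology analyzer), in
# cells per litre: five whole-blood samples measured both ways.
TABLE1_WBC = [
    (6.83e9, 6.93e9),
    (4.80e9, 4.86e9),
    (6.33e9, 6.29e9),
    (5.10e9, 5.22e9),
    (6.78e9, 6.96e9),
]
TABLE1_RBC = [
    (5.22e12, 5.35e12),
    (5.28e12, 5.36e12),
    (4.64e12, 4.73e12),
    (4.61e12, 4.68e12),
    (4.87e12, 4.74e12),
]


def geometry_numbers() -> dict:
    """Channel volume/area and sensor area from the printed dimensions."""
    geom = ChannelGeometry()  # 30 um x 150 um x 54.6 mm
    return {
        "channel_volume_uL": channel_volume_uL(geom),
        "channel_area_mm2": channel_area_mm2(geom),
        "sensor_area_mm2": sensor_area_mm2(1944, 2592, 2.2e-6),
    }


def instrument_comparison() -> dict:
    """Per-sample and average fractional errors against the reference
    hematology analyzer."""
    wbc = [compare_counts(ours, ref) for ours, ref in TABLE1_WBC]
    rbc = [compare_counts(ours, ref) for ours, ref in TABLE1_RBC]
    return {
        "wbc_errors_pct": wbc,
        "rbc_errors_pct": rbc,
        "wbc_mean_pct": round(float(np.mean(wbc)), 1),
        "rbc_mean_pct": round(float(np.mean(rbc)), 1),
    }


def counting_error_study(
    seed: int = 1,
    counts: tuple[int, ...] = (10, 50, 200),
    n_seeds: int = 3,
    grid: int = 512,
) -> dict:
    """Worst-case relative counting error of the full simulated pipeline.

    For every population size K and every phantom seed, a fresh frame of
    K well-separated cells is simulated at the default optics (465 nm,
    0.875 mm, 2.2 um pitch), degraded into a hologram, reconstructed
    with the phase-constrained variant (5 iterations, mask threshold
    0.34) and counted with the default segmentation settings.
    """
    optics = blue_led_optics((grid, grid))
    background = make_background(optics)
    cfg = ReconConfig(optics=optics)
    geom = ChannelGeometry()
    runs = []
    for k in counts:
        for offset in range(n_seeds):
            phantom = make_phantom(optics, k, seed=seed + offset)
            holo = forward_hologram(phantom, frame_id=f"K{k}_s{seed + offset}")
            result = count_frames([holo], background, cfg, geom)
            err = 100.0 * abs(result.count - k) / k
            runs.append(
                {"true": k, "seed": seed + offset, "counted": result.count,
                 "error_pct": err}
            )
    worst = max(r["error_pct"] for r in runs)
    return {"runs": runs, "worst_error_pct": worst, "n_runs": len(runs)}


def convergence_study(grid: int = 512, n_iterations: int = 8) -> dict:
    """Per-iteration reconstruction error of both variants on the dense
    leucocyte phantom, at the calibrated distance and at 20% deviation."""
    optics = blue_led_optics((grid, grid))
    phantom = make_leukocyte_phantom(optics)
    holo = forward_hologram(phantom)
    background = make_background(optics)
    out: dict = {}
    for label, override in (("calibrated", None), ("deviated_20pct", 1.2)):
        curves = {}
        for variant in ("classic", "phase_constrained"):
            cfg = ReconConfig(
                optics=optics,
                n_iterations=n_iterations,
                variant=variant,
                freeze_mask=True,
                distance_override=None if override is None
                else override * optics.distance_d,
            )
            res = reconstruct(holo, background, cfg, truth=phantom)
            curves[variant] = res.per_iteration_rmse
        out[label] = curves
    return out


def dilution_linearity_study(
    seed: int = 1,
    counts: tuple[int, ...] = (20, 40, 80, 120, 160),
    grid: int = 512,
) -> dict:
    """Linearity of estimated vs true cell load over a dilution series.

    Simulates frames whose true cell numbers span an 8x range (a
    dilution series at fixed channel volume), counts them with the
    default pipeline, and fits estimated = a * true + b by least
    squares; returns the fit and its R^2.
    """
    optics = blue_led_optics((grid, grid))
    background = make_background(optics)
    cfg = ReconConfig(optics=optics)
    geom = ChannelGeometry()
    true_counts, est_counts = [], []
    for i, k in enumerate(counts):
        phantom = make_phantom(optics, k, seed=seed + i)
        holo = forward_hologram(phantom)
        result = count_frames([holo], background, cfg, geom)
        true_counts.append(k)
        est_counts.append(result.count)
    x = np.asarray(true_counts, float)
    y = np.asarray(est_counts, float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return {
        "true_counts": true_counts,
        "estimated_counts": est_counts,
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": r2,
    }


def run_all(seed: int = 1) -> dict:
    """Everything the ``evaluate`` subcommand reports."""
    return {
        "geometry": geometry_numbers(),
        "instrument_comparison": instrument_comparison(),
        "counting": counting_error_study(seed=seed),
        "linearity": dilution_linearity_study(seed=seed),
        "convergence": convergence_study(),
    }
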