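"""Iterative twin-image suppression: constraints, initial estimates,
error metric, and convergence behaviour."""

import numpy as np
import pytest
from scipy import ndimage

from holocyte.optics import ComplexField, propagate
from holocyte.reconstruct import (
    ReconConfig,
    grey_scale,
    image_plane_constraint,
    initial_estimate_classic,
    initial_estimate_phase_constrained,
    normalize_amplitude,
    object_plane_constraint,
    reconstruct,
    rmse,
)
from holocyte.simulate import (
    Hologram,
    SensorModel,
    forward_hologram,
    make_background,
    make_leukocyte_phantom,
    make_phantom,
)


class TestRmse:
    def test_identical_images(self):
        a = np.random.default_rng(0).random((16, 16))
        assert rmse(a, a) == 0.0

    def test_constant_offset(self):
        a = np.zeros((8, 8))
        assert rmse(a, a + 0.37) == pytest.approx(0.37, abs=1e-14)

    def test_two_by_two_hand_computed(self):
        a = np.array([[0.0, 0.0], [0.0, 0.0]])
        b = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert rmse(a, b) == pytest.approx(0.5, abs=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros((4, 4)), np.zeros((4, 5)))


class TestInitialEstimates:
    def test_classic_is_back_propagated_measured_amplitude(self, optics_128):
        ph = make_phantom(optics_128, 3, seed=1)
        holo = forward_hologram(ph)
        cfg = ReconConfig(optics=optics_128)
        est = initial_estimate_classic(holo, cfg)
        manual = propagate(
            ComplexField(
                np.sqrt(holo.intensity).astype(complex), optics_128, "image"
            ),
            -optics_128.distance_d,
        )
        np.testing.assert_allclose(est.values, manual.values, atol=1e-12)

    def test_uniform_background_yields_empty_mask(self, optics_128):
        bg = make_background(optics_128)
        cfg = ReconConfig(optics=optics_128)
        res = reconstruct(bg, bg, cfg)
        assert not res.mask_C.any()

    def test_single_bead_dip_at_true_center(self, optics_128):
        ph = make_phantom(optics_128, 1, diameter_range_um=(7.0, 7.0), seed=3)
        holo = forward_hologram(ph)
        est = initial_estimate_classic(holo, ReconConfig(optics=optics_128))
        amp = normalize_amplitude(np.abs(est.values))
        deficit = np.clip(1.0 - amp, 0.0, None)
        main_dip = deficit * (deficit > 0.5 * deficit.max())
        com = ndimage.center_of_mass(main_dip)
        r, c, _, _ = ph.truth_cells[0]
        assert np.hypot(com[0] - r, com[1] - c) < 1.0

    def test_phase_constrained_reduces_to_classic_for_unit_intensity(
        self, optics_64
    ):
        holo = Hologram(np.ones(optics_64.grid_shape), optics_64)
        cfg = ReconConfig(optics=optics_64)
        classic = initial_estimate_classic(holo, cfg)
        seeded = initial_estimate_phase_constrained(holo, cfg)
        np.testing.assert_allclose(seeded.values, classic.values, atol=1e-12)

    def test_phase_constrained_constant_intensity_stays_constant(self, optics_64):
        c = 0.6
        holo = Hologram(np.full(optics_64.grid_shape, c), optics_64)
        cfg = ReconConfig(optics=optics_64)
        est = initial_estimate_phase_constrained(holo, cfg)
        mags = np.abs(est.values)
        np.testing.assert_allclose(mags, np.sqrt(c), atol=1e-12)

    def test_unnormalized_hologram_rejected(self, optics_64):
        holo = Hologram(np.full(optics_64.grid_shape, 2.0), optics_64)
        cfg = ReconConfig(optics=optics_64)
        with pytest.raises(ValueError, match="normalised"):
            initial_estimate_phase_constrained(holo, cfg)


class TestObjectPlaneConstraint:
    def test_scale_factor_unity_when_means_match(self, optics_64):
        bg = make_background(optics_64, SensorModel(noise_sd=0.0))
        level = bg.intensity.mean()
        u = ComplexField(np.full(optics_64.grid_shape, level + 0j), optics_64)
        out = object_plane_constraint(u, bg, np.zeros(optics_64.grid_shape, bool))
        np.testing.assert_allclose(out.values, bg.intensity, atol=1e-12)

    def test_all_cell_mask_leaves_field_unchanged(self, optics_64):
        bg = make_background(optics_64)
        rng = np.random.default_rng(2)
        u = ComplexField(
            rng.random(optics_64.grid_shape) + 1j * rng.random(optics_64.grid_shape),
            optics_64,
        )
        out = object_plane_constraint(u, bg, np.ones(optics_64.grid_shape, bool))
        np.testing.assert_allclose(out.values, u.values, atol=1e-14)

    def test_all_background_mask_gives_scaled_background_zero_phase(self, optics_64):
        bg = make_background(optics_64)
        u = ComplexField(
            np.full(optics_64.grid_shape, 0.5 * np.exp(1j * 0.3)), optics_64
        )
        out = object_plane_constraint(u, bg, np.zeros(optics_64.grid_shape, bool))
        m = np.mean(np.abs(u.values)) / np.mean(bg.intensity)
        np.testing.assert_allclose(out.values, m * bg.intensity, atol=1e-12)
        assert np.allclose(np.imag(out.values), 0.0)

    def test_zero_mean_background_rejected(self, optics_64):
        bg = Hologram(np.zeros(optics_64.grid_shape), optics_64, is_background=True)
        u = ComplexField(np.ones(optics_64.grid_shape), optics_64)
        with pytest.raises(ValueError, match="zero mean"):
            object_plane_constraint(u, bg, np.zeros(optics_64.grid_shape, bool))


class TestImagePlaneConstraint:
    def test_idempotent_when_amplitude_already_measured(self, optics_64):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, optics_64.grid_shape)
        measured = rng.uniform(0.5, 1.0, optics_64.grid_shape)
        u = ComplexField(measured * np.exp(1j * phase), optics_64, "image")
        out = image_plane_constraint(u, measured)
        np.testing.assert_allclose(out.values, u.values, atol=1e-12)

    def test_amplitude_replaced_phase_kept(self, optics_64):
        rng = np.random.default_rng(4)
        u = ComplexField(
            rng.random(optics_64.grid_shape) * np.exp(1j * rng.random(optics_64.grid_shape)),
            optics_64,
            "image",
        )
        measured = rng.uniform(0.2, 1.0, optics_64.grid_shape)
        out = image_plane_constraint(u, measured)
        np.testing.assert_allclose(np.abs(out.values), measured, atol=1e-12)
        np.testing.assert_allclose(
            np.angle(out.values), np.angle(u.values), atol=1e-12
        )

    def test_shape_mismatch_rejected(self, optics_64):
        u = ComplexField(np.ones(optics_64.grid_shape), optics_64, "image")
        with pytest.raises(ValueError):
            image_plane_constraint(u, np.ones((32, 32)))


class TestGreyScale:
    def test_flat_frame_has_no_dark_pixels(self):
        g = grey_scale(np.full((32, 32), 0.95))
        assert (g >= 1.0).all()

    def test_stretched_range_spans_unit_interval(self):
        rng = np.random.default_rng(5)
        amp = np.ones((64, 64))
        amp[10:20, 10:20] = 0.3  # a dark object on unit background
        amp += rng.normal(0, 1e-3, amp.shape)
        g = grey_scale(amp)
        assert g.min() == pytest.approx(0.0, abs=1e-6)
        assert g.max() == pytest.approx(1.0, abs=1e-6)


class TestReconstructEndToEnd:
    def test_background_frame_reconstructs_to_empty_mask(
        self, optics_256, background_256
    ):
        res = reconstruct(background_256, background_256, ReconConfig(optics=optics_256))
        assert not res.mask_C.any()
        assert np.ptp(res.amplitude_image) < 0.05

    def test_phase_variant_rmse_monotone_on_sparse_phantom(
        self, optics_256, background_256
    ):
        ph = make_phantom(optics_256, 12, seed=7)
        holo = forward_hologram(ph)
        cfg = ReconConfig(optics=optics_256, n_iterations=5)
        res = reconstruct(holo, background_256, cfg, truth=ph)
        r = res.per_iteration_rmse
        assert len(r) == 5
        assert all(r[i + 1] <= r[i] + 1e-9 for i in range(len(r) - 1))

    def test_first_iteration_improves_on_initial_estimate(
        self, optics_256, background_256
    ):
        ph = make_leukocyte_phantom(optics_256)
        holo = forward_hologram(ph)
        for variant in ("classic", "phase_constrained"):
            cfg = ReconConfig(optics=optics_256, variant=variant, freeze_mask=True)
            res = reconstruct(holo, background_256, cfg, truth=ph)
            assert res.per_iteration_rmse[0] < res.initial_rmse

    def test_phase_constrained_beats_classic_under_distance_deviation(
        self, optics_256, background_256
    ):
        ph = make_leukocyte_phantom(optics_256)
        holo = forward_hologram(ph)
        finals = {}
        for variant in ("classic", "phase_constrained"):
            cfg = ReconConfig(
                optics=optics_256,
                variant=variant,
                freeze_mask=True,
                distance_override=1.2 * optics_256.distance_d,
            )
            res = reconstruct(holo, background_256, cfg, truth=ph)
            finals[variant] = res.per_iteration_rmse[-1]
        assert finals["phase_constrained"] < finals["classic"]

    def test_ghost_energy_outside_cells_decreases(self, optics_256, background_256):
        """Twin-image suppression: the ghost-ring variance outside the
        cell region shrinks between the first and the final iteration on
        a micro-bead frame (its rings lie well outside the bead)."""
        ph = make_phantom(optics_256, 1, diameter_range_um=(7.0, 7.0), seed=5)
        holo = forward_hologram(ph)
        outside = ~ndimage.binary_dilation(ph.transmittance > 0.01, iterations=6)
        variances = {}
        for n in (1, 5):
            res = reconstruct(
                holo, background_256, ReconConfig(optics=optics_256, n_iterations=n)
            )
            variances[n] = np.var(res.amplitude_image[outside])
        assert variances[5] < variances[1]

    def test_early_stop_on_tolerance(self, optics_256, background_256):
        ph = make_phantom(optics_256, 5, seed=2)
        holo = forward_hologram(ph)
        cfg = ReconConfig(optics=optics_256, n_iterations=30, tol=1e-3)
        res = reconstruct(holo, background_256, cfg)
        assert res.n_iterations_run < 30

    def test_mismatched_shapes_rejected(self, optics_256, optics_128):
        holo = make_background(optics_256)
        bg = make_background(optics_128)
        with pytest.raises(ValueError):
            reconstruct(holo, bg, ReconConfig(optics=optics_256))

    def test_config_validation(self, optics_64):
        with pytest.raises(ValueError):
            ReconConfig(optics=optics_64, n_iterations=0)
        with pytest.raises(ValueError):
            ReconConfig(optics=optics_64, threshold=1.5)
        with pytest.raises(ValueError):
            ReconConfig(optics=optics_64, variant="bogus")
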