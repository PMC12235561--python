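"""Reconstruction steps: navigator solve, phase smoothing, ADMM behavior."""

import warnings

import numpy as np
import pandas as pd
import pytest

from msdwi import (
    JointReconstruction,
    LLRConfig,
    ProtocolSpec,
    SamplingPattern,
    adjoint_E2,
    apply_E1,
    apply_E2,
    estimate_shot_phase,
    hanning_smooth,
    joint_reconstruct,
    make_coil_maps,
    nrmse,
    solve_navigator,
)
from msdwi.dataset import Acquisition
from msdwi.recon import ConfigurationError, _cg, admm_solve, extract_self_navigator


def _crandn(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestNavigatorSolve:
    def test_unitary_system_exact_recovery(self):
        rng = np.random.default_rng(0)
        p = ProtocolSpec(matrix=(16, 16))
        pattern = SamplingPattern(np.ones((2, 1, 16), dtype=np.uint8))
        maps = np.ones((1, 1, 16, 16), dtype=complex)
        x = _crandn(rng, (2, 1, 1, 16, 16))
        y = apply_E1(x, maps, pattern, p)
        out = solve_navigator(y, maps, pattern, p, lam_l2=0.0)
        assert nrmse(out, x) < 1e-6

    def test_huge_regularization_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        p = ProtocolSpec(matrix=(8, 8))
        pattern = SamplingPattern(np.ones((1, 1, 8), dtype=np.uint8))
        maps = np.ones((1, 1, 8, 8), dtype=complex)
        y = apply_E1(_crandn(rng, (1, 1, 1, 8, 8)), maps, pattern, p)
        out = solve_navigator(y, maps, pattern, p, lam_l2=1e6)
        assert np.linalg.norm(out) < 1e-4 * np.linalg.norm(y)

    def test_eight_coil_r2_phantom_recovery(self):
        rng = np.random.default_rng(1)
        ny = 24
        p = ProtocolSpec(matrix=(ny, ny), r_inplane=2)
        masks = np.zeros((1, 1, ny), dtype=np.uint8)
        masks[:, :, ::2] = 1
        maps = make_coil_maps(8, (1, ny, ny), seed=2)
        yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, ny), indexing="ij")
        img = ((yy**2 + xx**2) < 0.64).astype(complex) * (1 + 0.3 * xx)
        x = img[None, None, None]
        y = apply_E1(x, maps, masks, p)
        out = solve_navigator(y, maps, masks, p, lam_l2=1e-6, n_cg=200)
        assert nrmse(out, x) < 1e-2


class TestSelfNavigator:
    def test_central_quarter_extraction(self):
        y = np.arange(2 * 3 * 2 * 64 * 64, dtype=float).reshape(2, 3, 2, 64, 64) + 0j
        masks = np.ones((3, 2, 64), dtype=np.uint8)
        y_nav, nav_masks, grid = extract_self_navigator(y, masks, ProtocolSpec(matrix=(64, 64)))
        assert grid == (16, 16)
        assert y_nav.shape == (2, 3, 2, 16, 16)
        np.testing.assert_array_equal(y_nav, y[:, :, :, 24:40, 24:40])

    def test_zero_input_zero_output_and_energy(self):
        rng = np.random.default_rng(0)
        p = ProtocolSpec(matrix=(32, 32))
        masks = np.ones((1, 1, 32), dtype=np.uint8)
        y = _crandn(rng, (2, 1, 1, 32, 32))
        y_nav, _, _ = extract_self_navigator(y, masks, p)
        assert np.linalg.norm(y_nav) <= np.linalg.norm(y)
        z_nav, _, _ = extract_self_navigator(np.zeros_like(y), masks, p)
        assert np.all(z_nav == 0)

    def test_non_divisible_grid_rounds_down_with_warning(self):
        p = ProtocolSpec(matrix=(18, 18), n_shots=2, r_inplane=3)
        y = np.zeros((1, 1, 2, 18, 18), dtype=complex)
        masks = np.ones((1, 2, 18), dtype=np.uint8)
        with pytest.warns(RuntimeWarning):
            _, _, grid = extract_self_navigator(y, masks, p)
        assert grid == (4, 4)


class TestHanningSmoothing:
    def test_k0_is_identity(self):
        rng = np.random.default_rng(0)
        img = _crandn(rng, (5, 9, 11))
        np.testing.assert_array_equal(hanning_smooth(img, 0), img)

    @pytest.mark.parametrize("K", [1, 5, 20])
    def test_constant_image_unchanged(self, K):
        img = (2.0 - 1.0j) * np.ones((16, 16))
        np.testing.assert_allclose(hanning_smooth(img, K), img, atol=1e-12)

    def test_low_frequency_linear_phase_preserved_inside_support(self):
        ny = nx = 32
        yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
        support = (yy**2 + xx**2) < 0.6
        img = support * np.exp(1j * (0.5 * yy + 0.8 * xx))
        sm = hanning_smooth(img, 5)
        err = np.angle(sm * np.conj(img))[support]
        assert np.sqrt(np.mean(err**2)) < 0.05

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            hanning_smooth(np.zeros((4, 4)), -1)


class TestShotPhaseEstimation:
    def test_zero_phase_in_zero_phase_out(self):
        nav = np.ones((2, 3, 1, 16, 16), dtype=complex)
        phi = estimate_shot_phase(nav, 5, (32, 32))
        np.testing.assert_allclose(phi, 1.0, atol=1e-12)

    def test_unit_modulus_everywhere(self):
        rng = np.random.default_rng(0)
        nav = _crandn(rng, (2, 2, 1, 16, 16))
        phi = estimate_shot_phase(nav, 3, (48, 48))
        np.testing.assert_allclose(np.abs(phi), 1.0, atol=1e-12)

    def test_quadratic_ramp_difference_recovered(self):
        ny = 32
        yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, ny), indexing="ij")
        mag = ((yy**2 + xx**2) < 0.7).astype(float) + 0.01
        ramp = 0.8 * (yy**2 - 0.5 * xx * yy + xx)
        nav = np.stack([mag + 0j, mag * np.exp(1j * ramp)])[None, :, None]
        phi = estimate_shot_phase(nav, 5, (ny, ny))
        diff = np.angle(phi[0, 1, 0] * np.conj(phi[0, 0, 0]))
        support = mag > 0.5
        err = (diff - ramp)[support]
        assert np.sqrt(np.mean(err**2)) < 0.1


class TestADMM:
    def test_objective_history_columns(self, p1_recon_known_phases):
        hist = p1_recon_known_phases.history
        assert {"iteration", "data_consistency", "nuclear_norm", "objective"} <= set(hist.columns)
        assert len(hist[hist.batch == 0]) == 15

    def test_zero_data_returns_zero(self):
        p = ProtocolSpec(matrix=(8, 8))
        masks = np.ones((1, 1, 8), dtype=np.uint8)
        maps = np.ones((1, 1, 8, 8), dtype=complex)
        phi = np.ones((1, 1, 1, 8, 8), dtype=complex)
        x, hist = admm_solve(np.zeros((1, 1, 1, 8, 8), dtype=complex), phi, maps, masks, p, LLRConfig(block_width=4))
        assert np.all(x == 0)

    def test_cg_solves_small_spd_system(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        A = A.conj().T @ A + 0.5 * np.eye(6)
        b = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        x, conv = _cg(lambda v: A @ v, b, n_iter=50, tol=1e-12)
        assert conv
        np.testing.assert_allclose(A @ x, b, atol=1e-8)


class TestPipeline:
    def test_missing_navigator_multishot_raises(self):
        p = ProtocolSpec(matrix=(8, 8), n_shots=2, nav_matrix=(4, 4))
        data = Acquisition(
            y=np.zeros((1, 1, 2, 8, 8), dtype=complex),
            maps=np.ones((1, 1, 8, 8), dtype=complex),
            pattern=SamplingPattern.from_protocol(p, 1),
            protocol=p,
        )
        with pytest.raises(ConfigurationError):
            joint_reconstruct(data, LLRConfig(block_width=4))

    def test_single_shot_unit_phase_equals_admm_alone(self):
        rng = np.random.default_rng(0)
        p = ProtocolSpec(matrix=(12, 12), r_inplane=2, nav_matrix=(6, 6))
        masks = SamplingPattern.from_protocol(p, 3)
        maps = make_coil_maps(4, (1, 12, 12), seed=0)
        x_true = _crandn(rng, (3, 1, 12, 12))
        phi = np.ones((3, 1, 1, 12, 12), dtype=complex)
        y = apply_E2(x_true, phi, maps, masks, p)
        data = Acquisition(y=y, maps=maps, pattern=masks, protocol=p)
        cfg = LLRConfig(lam=0.001, block_width=4)
        res = joint_reconstruct(data, cfg)
        direct, _ = admm_solve(y, phi, maps, masks.masks, p, cfg)
        np.testing.assert_allclose(res.x_tilde, direct, atol=1e-10)

    def test_batch_split_matches_unsplit_without_regularizer(self, p1_noiseless):
        phi = p1_noiseless.truth["phases"]
        r1 = joint_reconstruct(p1_noiseless, LLRConfig(lam=0.0, n_batches=1), phases=phi)
        r3 = joint_reconstruct(p1_noiseless, LLRConfig(lam=0.0, n_batches=3), phases=phi)
        assert nrmse(r3.x_tilde, r1.x_tilde) < 1e-6

    def test_summary_reports_configuration(self, p1_recon_known_phases):
        text = p1_recon_known_phases.summary()
        assert "lambda" in text and "ADMM iterations" in text
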