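"""Synthetic acquisition generator and the diffusion-tensor fit."""

import numpy as np
import pytest

from msdwi import (
    DiffusionScheme,
    SimulationConfig,
    dwi_signal,
    fa_from_tensors,
    make_acquisition_schedule,
    make_coil_maps,
    make_diffusion_scheme,
    make_phantom,
    make_shot_phases,
    protocol1_analog,
    protocol3_analog,
    retrospective_undersample,
    simulate_acquisition,
    tensor_fit,
)


class TestPhantom:
    def test_deterministic(self):
        a = make_phantom((2, 24, 24), seed=3)
        b = make_phantom((2, 24, 24), seed=3)
        np.testing.assert_array_equal(a.s0, b.s0)
        np.testing.assert_array_equal(a.tensors, b.tensors)

    def test_tensors_positive_semidefinite(self):
        t = make_phantom((1, 32, 32), seed=0).tensors
        assert np.linalg.eigvalsh(t).min() >= -1e-18

    def test_has_anisotropic_and_isotropic_compartments(self):
        ph = make_phantom((1, 32, 32), seed=0)
        fa = fa_from_tensors(ph.tensors)
        for c, lo, hi in [(1, 0.5, 1.0), (2, 0.0, 0.1)]:
            vals = fa[ph.labels == c]
            assert vals.size > 0
            assert lo <= vals.mean() <= hi

    def test_s0_zero_outside_support(self):
        ph = make_phantom((2, 24, 24), seed=1)
        assert np.all(ph.s0[~ph.support] == 0)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            make_phantom((1, 8, 32), seed=0)


class TestSignalModel:
    @pytest.fixture
    def phantom(self):
        return make_phantom((1, 24, 24), seed=0)

    def test_b0_returns_s0(self, phantom):
        np.testing.assert_array_equal(dwi_signal(phantom, 0.0, None), phantom.s0)

    def test_isotropic_signal_direction_independent(self, phantom):
        iso = phantom.labels == 2
        s1 = dwi_signal(phantom, 1000.0, [1.0, 0, 0])
        s2 = dwi_signal(phantom, 1000.0, [0, 1 / np.sqrt(2), 1 / np.sqrt(2)])
        np.testing.assert_allclose(s1[iso], s2[iso], rtol=1e-12)

    def test_unit_adc_attenuation(self, phantom):
        # isotropic d = 0.8e-3 mm^2/s at b = 1250 -> exp(-1)
        iso = phantom.labels == 2
        s = dwi_signal(phantom, 1250.0, [1.0, 0, 0])
        np.testing.assert_allclose(
            np.abs(s[iso]) / phantom.s0[iso], np.exp(-1.0), rtol=1e-12
        )

    def test_non_unit_direction_rejected(self, phantom):
        with pytest.raises(ValueError):
            dwi_signal(phantom, 1000.0, [1.0, 1.0, 0.0])


class TestCoilMaps:
    def test_single_coil_constant_unit(self):
        np.testing.assert_array_equal(
            make_coil_maps(1, (2, 8, 8), seed=0), np.ones((1, 2, 8, 8))
        )

    def test_rss_normalized(self):
        maps = make_coil_maps(8, (2, 16, 16), seed=1)
        rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        np.testing.assert_allclose(rss, 1.0, atol=1e-6)

    def test_deterministic_and_band_dependent(self):
        a = make_coil_maps(4, (2, 16, 16), seed=5)
        b = make_coil_maps(4, (2, 16, 16), seed=5)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a[:, 0], a[:, 1])


class TestShotPhases:
    def cfg(self, amp):
        return SimulationConfig(
            protocol=protocol1_analog((24, 24)), phase_amplitude=amp, seed=2
        )

    def test_zero_amplitude_gives_unit_phase(self):
        phi = make_shot_phases(self.cfg(0.0), n_encodings=3)
        np.testing.assert_array_equal(phi, np.ones_like(phi))

    def test_unit_modulus_and_reference_shot(self):
        phi = make_shot_phases(self.cfg(1.0), n_encodings=4)
        np.testing.assert_allclose(np.abs(phi), 1.0, atol=1e-12)
        np.testing.assert_array_equal(phi[:, 0], np.ones_like(phi[:, 0]))

    def test_rms_phase_scales_linearly_with_amplitude(self):
        p1 = make_shot_phases(self.cfg(0.5), n_encodings=4)
        p2 = make_shot_phases(self.cfg(1.0), n_encodings=4)
        r1 = np.sqrt(np.mean(np.angle(p1[:, 1:]) ** 2))
        r2 = np.sqrt(np.mean(np.angle(p2[:, 1:]) ** 2))
        assert r2 / r1 == pytest.approx(2.0, rel=1e-6)


class TestSimulateAcquisition:
    def test_bitwise_deterministic(self):
        cfg = SimulationConfig(protocol=protocol3_analog(), noise_sigma=0.03, seed=8)
        a = simulate_acquisition(cfg)
        b = simulate_acquisition(cfg)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.y_nav, b.y_nav)

    def test_sampled_entry_count(self, p1_noiseless):
        p = p1_noiseless.protocol
        nc, nq, ns, ny, nx = p1_noiseless.y.shape
        expected = nc * nq * ns * nx * (ny // (p.r_inplane * p.n_shots))
        assert int(p1_noiseless.pattern.masks.sum()) * nc * nx == expected

    def test_unsampled_entries_zero(self, p1_noiseless):
        off = p1_noiseless.pattern.masks == 0
        moved = p1_noiseless.y.transpose(1, 2, 3, 0, 4)
        assert np.all(moved[off] == 0)

    def test_navigator_present_for_navigated_protocol(self, p1_noiseless):
        assert p1_noiseless.y_nav is not None
        assert p1_noiseless.y_nav.shape[-2:] == p1_noiseless.protocol.nav_matrix


class TestRetrospectiveUndersampling:
    def test_keep_all_is_identity(self, p1_noiseless):
        red = retrospective_undersample(p1_noiseless, 4)
        assert red is p1_noiseless

    def test_without_shift_every_encoding_same_lines(self, p1_noiseless):
        red = retrospective_undersample(p1_noiseless, 1, ky_shift=False)
        lines = [tuple(np.nonzero(m[0])[0]) for m in red.pattern.masks]
        assert len(set(lines)) == 1

    def test_with_shift_lines_cycle_by_one(self, p1_noiseless):
        red = retrospective_undersample(p1_noiseless, 1, ky_shift=True)
        dw = np.nonzero(red.scheme.bvals > 0)[0]
        a = np.nonzero(red.pattern.masks[dw[0], 0])[0]
        b = np.nonzero(red.pattern.masks[dw[1], 0])[0]
        ny = red.protocol.ny
        assert set((a + 1) % ny) == set(b)

    def test_too_many_shots_rejected(self, p1_noiseless):
        with pytest.raises(ValueError):
            retrospective_undersample(p1_noiseless, 5)


class TestTensorFit:
    def _scheme(self, n=20, seed=0):
        return make_acquisition_schedule(make_diffusion_scheme([(1000, n)], seed=seed), 10)

    def test_exact_recovery_noiseless(self):
        ph = make_phantom((1, 24, 24), seed=0)
        sched = self._scheme()
        mags = np.stack([np.abs(dwi_signal(ph, b, g)) for b, g in zip(sched.bvals, sched.bvecs)])[:, :]
        tensors, fa = tensor_fit(mags, sched, support=ph.support)
        m = ph.support
        err = np.abs(tensors[m] - ph.tensors[m]).max()
        assert err < 1e-8 * np.abs(ph.tensors[m]).max()

    def test_isotropic_fa_zero(self):
        ph = make_phantom((1, 24, 24), seed=0)
        sched = self._scheme()
        mags = np.stack([np.abs(dwi_signal(ph, b, g)) for b, g in zip(sched.bvals, sched.bvecs)])
        _, fa = tensor_fit(mags, sched, support=ph.support)
        assert np.all(np.abs(fa[ph.labels == 2]) < 1e-10)

    def test_anisotropic_fa_within_005_at_snr20_monte_carlo(self):
        ph = make_phantom((1, 24, 24), seed=0)
        sched = self._scheme()
        clean = np.stack([dwi_signal(ph, b, g) for b, g in zip(sched.bvals, sched.bvecs)])
        rng = np.random.default_rng(12)
        mask = ph.labels == 1
        fa_true = fa_from_tensors(ph.tensors[mask].mean(axis=0))
        sigma = 1.0 / 20.0
        estimates = []
        for _ in range(100):
            noisy = np.abs(
                clean + sigma * (rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)) / np.sqrt(2)
            )
            tensors, _ = tensor_fit(noisy, sched, support=ph.support)
            estimates.append(float(fa_from_tensors(tensors[mask].mean(axis=0))))
        assert abs(np.mean(estimates) - fa_true) < 0.05

    def test_insufficient_directions_rejected(self):
        sched = DiffusionScheme([0, 1000, 1000], [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(ValueError):
            tensor_fit(np.ones((3, 1, 16, 16)), sched)

    def test_nonpositive_voxels_skipped(self):
        ph = make_phantom((1, 24, 24), seed=0)
        sched = self._scheme(n=8)
        mags = np.stack([np.abs(dwi_signal(ph, b, g)) for b, g in zip(sched.bvals, sched.bvecs)])
        mags[0, 0, 12, 12] = 0.0
        tensors, fa = tensor_fit(mags, sched, support=ph.support)
        assert fa[0, 12, 12] == 0.0
        assert np.all(tensors[0, 12, 12] == 0.0)


class TestNoiseMonotonicity:
    def test_reconstruction_error_increases_with_noise(self):
        from msdwi import JointReconstruction, LLRConfig, nrmse

        errs = []
        for sigma in [0.0, 0.05, 0.15]:
            cfg = SimulationConfig(protocol=protocol3_analog((20, 20)), noise_sigma=sigma, seed=4)
            data = simulate_acquisition(cfg)
            res = JointReconstruction(
                data, LLRConfig(lam=0.0, n_admm=5), phases=data.truth["phases"]
            ).fit()
            errs.append(nrmse(res.magnitude, np.abs(data.truth["dwis"])))
        assert errs[0] < errs[1] < errs[2]
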