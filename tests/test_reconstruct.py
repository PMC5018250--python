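"""IHRSR engine components: boxing, CTF handling, alignment,
back-projection, symmetry search/imposition, alignment transfer."""

import numpy as np
import pandas as pd
import pytest

from conftest import corr
from helifil.ctf import AcquisitionParams, CtfParams, ctf_2d
from helifil.fsc import fsc
from helifil.reconstruct import (
    AlignmentParams,
    BoxingParams,
    align_segments,
    backproject,
    cyclic_symmetry_residual,
    extract_overlapping_boxes,
    ihrsr,
    make_cylinder_volume,
    make_references,
    phase_flip,
    sort_segments,
    symmetrize,
    symmetry_search,
    transfer_alignment,
)
from helifil.simulate import project_volume, simulate_segment_stack
from helifil.symmetry import HelicalSymmetry
from helifil.volume import META_COLUMNS, DensityVolume, SegmentStack
from helifil.voxel_ops import rotate_volume_z, screw_transform_volume


def _stack_from_images(images, pixel_size=3.0, defocus=np.nan):
    meta = pd.DataFrame(
        {c: (defocus if c == "defocus_A" else 0.0) for c in META_COLUMNS},
        index=range(len(images)),
    )
    return SegmentStack(np.asarray(images, dtype=np.float32), meta, pixel_size)


class TestBoxing:
    @pytest.mark.parametrize(
        "length, expected",
        [(384, 1), (402, 2), (384 + 10 * 18, 11)],
    )
    def test_box_counts(self, length, expected):
        img = np.random.default_rng(0).standard_normal((length, 384)).astype(np.float32)
        stack = extract_overlapping_boxes(img, BoxingParams(384, 18))
        assert len(stack) == expected
        assert list(stack.meta["box_offset_px"]) == [i * 18 for i in range(expected)]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            extract_overlapping_boxes(np.zeros((100, 384), np.float32), BoxingParams(384, 18))

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            BoxingParams(384, 0)


class TestPhaseFlip:
    def test_zero_image_stays_zero(self, acq_desk):
        stack = _stack_from_images(np.zeros((2, 32, 32)), defocus=15000.0)
        out = phase_flip(stack, acq_desk)
        assert np.allclose(out.images, 0.0)
        assert out.ctf_flipped

    def test_missing_defocus_raises(self, acq_desk):
        stack = _stack_from_images(np.zeros((1, 32, 32)), defocus=np.nan)
        with pytest.raises(ValueError):
            phase_flip(stack, acq_desk)

    def test_double_application_is_ctf_squared(self, acq_desk):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((32, 32)).astype(np.float32)
        stack = _stack_from_images([img], defocus=20000.0)
        twice = phase_flip(phase_flip(stack, acq_desk), acq_desk)
        H = ctf_2d(CtfParams(20000.0), acq_desk, (32, 32), 3.0)
        expect = np.fft.irfft2(np.fft.rfft2(img) * H * H, s=(32, 32))
        assert np.allclose(twice.images[0], expect, atol=1e-4)

    def test_flipped_projection_matches_forward_filter_oracle(self, volume64, acq_desk):
        proj = project_volume(volume64, 40.0).astype(np.float32)
        stack = _stack_from_images([proj], defocus=18000.0)
        flipped = phase_flip(stack, acq_desk)
        H = ctf_2d(CtfParams(18000.0), acq_desk, proj.shape, 3.0)
        oracle = np.fft.irfft2(np.fft.rfft2(proj) * H, s=proj.shape)
        assert corr(flipped.images[0], oracle) > 0.999


class TestReferences:
    def test_c5_four_degree_step_gives_18(self, volume64, ped208_sym):
        refs = make_references(volume64, ped208_sym, 4.0)
        assert len(refs) == 18
        assert refs[0][0] == 0.0 and refs[-1][0] == pytest.approx(68.0)

    def test_c1_ninety_degree_step_gives_4(self, volume64):
        refs = make_references(volume64, HelicalSymmetry(28.2, 12.1, 1), 90.0)
        assert len(refs) == 4

    def test_symmetry_equivalent_azimuths_identical(self, volume64, ped208_sym):
        sym_vol = symmetrize(volume64, ped208_sym)
        a = project_volume(sym_vol, 10.0)
        b = project_volume(sym_vol, 82.0)
        assert corr(a, b) > 0.999

    def test_invalid_step(self, volume64, ped208_sym):
        with pytest.raises(ValueError):
            make_references(volume64, ped208_sym, 0.0)


class TestAlign:
    def test_identical_image_scores_unity_at_zero_shift(self, volume64):
        ref = project_volume(volume64, 8.0)
        stack = _stack_from_images([ref])
        params = align_segments(stack, [(8.0, ref)], (2, 2))
        assert params.score[0] == pytest.approx(1.0, abs=1e-5)
        assert params.shift_x_px[0] == 0 and params.shift_z_px[0] == 0

    def test_noiseless_projections_recovered(self, volume64, ped208_sym):
        # a z-shift by one rise equals an azimuth change by one twist, so
        # recovered (azimuth, z-shift) pairs are scored modulo that
        # helical degeneracy
        sym_vol = symmetrize(volume64, ped208_sym)
        refs = make_references(sym_vol, ped208_sym, 4.0)
        rng = np.random.default_rng(5)
        azs = rng.uniform(0, 360, 40)
        dzs = rng.integers(-3, 4, 40)
        dxs = rng.integers(-3, 4, 40)
        imgs = [
            project_volume(sym_vol, az, shift_px=(dz, dx))
            for az, dz, dx in zip(azs, dzs, dxs)
        ]
        params = align_segments(_stack_from_images(imgs), refs, (4, 4))
        rise_px = ped208_sym.rise_A / 3.0
        ok = np.zeros(len(azs), dtype=bool)
        for k in (-1, 0, 1):
            az_eq = azs + k * ped208_sym.twist_deg
            dz_eq = dzs + k * rise_px
            d_az = np.abs((params.azimuth_deg - az_eq + 36.0) % 72.0 - 36.0)
            ok |= (
                (d_az <= 2.0)
                & (np.abs(params.shift_z_px - dz_eq) <= 1)
                & (np.abs(params.shift_x_px - dxs) <= 1)
            )
        assert ok.mean() >= 0.95

    def test_empty_stack_raises(self, volume64):
        stack = _stack_from_images(np.zeros((0, 64, 64)))
        with pytest.raises(ValueError):
            align_segments(stack, [(0.0, np.zeros((64, 64)))])


class TestBackproject:
    def test_even_views_round_trip_fsc(self, volume64):
        azs = np.arange(0.0, 360.0, 2.0)
        imgs = [project_volume(volume64, az) for az in azs]
        stack = _stack_from_images(imgs)
        params = AlignmentParams(
            azs, np.zeros(len(azs)), np.zeros(len(azs)), np.zeros(len(azs)), np.ones(len(azs))
        )
        rec = backproject(stack, params)
        curve = fsc(volume64, rec)
        half = len(curve.frequencies) // 2
        assert np.all(curve.correlations[1:half] > 0.95)

    def test_zero_images_give_zero_volume(self):
        stack = _stack_from_images(np.zeros((4, 32, 32)))
        params = AlignmentParams(
            np.array([0.0, 10.0, 20.0, 30.0]), np.zeros(4), np.zeros(4), np.zeros(4), np.ones(4)
        )
        rec = backproject(stack, params)
        assert np.allclose(rec.data, 0.0)

    def test_ctf_correction_restores_low_frequencies(self, volume64, acq_desk):
        from helifil.voxel_ops import radial_spectrum_3d

        stk = simulate_segment_stack(
            volume64, 60, acq_desk, defocus_range_um=(1.0, 2.5), noise_sigma=0.0,
            seed=8, rise_A=None, tilt_jitter_deg=0.0,
        )
        flipped = phase_flip(stk, acq_desk)
        n = len(stk)
        az = np.round(stk.meta["azimuth_deg"].to_numpy() / 4) * 4 % 360
        params = AlignmentParams(az, np.zeros(n), np.zeros(n), np.zeros(n), np.ones(n))
        raw = SegmentStack(flipped.images, flipped.meta, 3.0, ctf_flipped=False)
        no_corr = backproject(raw, params)
        corrected = backproject(flipped, params, acq=acq_desk)
        f, amp_no = radial_spectrum_3d(no_corr.data, 3.0)
        _, amp_yes = radial_spectrum_3d(corrected.data, 3.0)
        # inside the first CTF lobe the uncorrected amplitudes are suppressed
        lobe = (f > 0.0) & (f < 0.03)
        ratio = amp_no[lobe].sum() / amp_yes[lobe].sum()
        norm = amp_no[f > 0].sum() / amp_yes[f > 0].sum()
        assert ratio / norm < 1.0

    def test_mismatched_alignment_raises(self, volume64):
        stack = _stack_from_images(np.zeros((3, 64, 64)))
        params = AlignmentParams(np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            backproject(stack, params)


class TestSymmetrySearch:
    def test_clean_volume_recovery(self, volume96):
        res = symmetry_search(volume96, HelicalSymmetry(27.0, 11.5, 5))
        assert res.symmetry.twist_deg == pytest.approx(28.2, abs=0.1)
        assert res.symmetry.rise_A == pytest.approx(12.1, abs=0.05)
        assert not res.degenerate

    def test_constant_volume_degenerate(self):
        vol = DensityVolume(np.ones((48, 48, 48), np.float32), 3.0)
        res = symmetry_search(vol, HelicalSymmetry(27.0, 11.5, 5))
        assert res.degenerate

    def test_wrong_cyclic_order_has_higher_residual(self, volume96):
        r5 = cyclic_symmetry_residual(volume96, 5)
        r4 = cyclic_symmetry_residual(volume96, 4)
        assert r4 > 5 * r5


class TestSymmetrize:
    def test_idempotent(self, volume64, ped208_sym):
        once = symmetrize(volume64, ped208_sym)
        twice = symmetrize(once, ped208_sym)
        assert corr(once.data, twice.data) > 0.999

    def test_output_invariant_under_lattice_ops(self, volume64, ped208_sym):
        from helifil.voxel_ops import cylinder_mask

        sym_vol = symmetrize(volume64, ped208_sym)
        mask = cylinder_mask(sym_vol.data.shape, 3.0, 0, 45, z_margin_A=16.0)
        rot = rotate_volume_z(sym_vol.data, 72.0, order=3)
        assert corr(sym_vol.data[mask], rot[mask]) > 0.999
        screwed = screw_transform_volume(sym_vol.data, 28.2, 12.1 / 3.0, order=3)
        assert corr(sym_vol.data[mask], screwed[mask]) > 0.999

    def test_symmetrizing_noise_creates_symmetry(self, ped208_sym):
        # band-limited noise (as produced by any filtered reconstruction);
        # raw white noise would only measure interpolation attenuation
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(0)
        noise = DensityVolume(
            gaussian_filter(rng.standard_normal((64, 64, 64)).astype(np.float32), 1.0), 3.0
        )
        before = corr(noise.data, rotate_volume_z(noise.data, 72.0))
        sym_vol = symmetrize(noise, ped208_sym)
        from helifil.voxel_ops import cylinder_mask

        mask = cylinder_mask(sym_vol.data.shape, 3.0, 0, 45, z_margin_A=16.0)
        after = corr(sym_vol.data[mask], rotate_volume_z(sym_vol.data, 72.0, order=3)[mask])
        assert abs(before) < 0.1
        assert after > 0.99


class TestIhrsrBasics:
    def test_zero_iterations_returns_initial_state(self, volume64, acq_desk, ped208_sym):
        stk = simulate_segment_stack(volume64, 4, acq_desk, seed=1, rise_A=12.1, target_snr=1.0)
        init = make_cylinder_volume(64, 3.0)
        state = ihrsr(stk, init, ped208_sym, max_iter=0)
        assert state.iteration == 0
        assert not state.converged
        assert state.history == [(28.2, 12.1)]
        assert np.array_equal(state.volume.data, init.data)

    def test_noiseless_segments_converge_quickly(self, volume64, acq_desk, ped208_sym):
        stk = simulate_segment_stack(
            volume64, 60, acq_desk, seed=2, rise_A=12.1, noise_sigma=0.0, tilt_jitter_deg=0.0
        )
        stk = phase_flip(stk, acq_desk)
        init = make_cylinder_volume(64, 3.0, radius_A=40.0, noise_sd=0.1, seed=3)
        state = ihrsr(
            stk, init, HelicalSymmetry(27.5, 11.8, 5), max_iter=5, acq=acq_desk,
        )
        assert state.converged and state.iteration <= 5
        assert state.symmetry.twist_deg == pytest.approx(28.2, abs=0.3)
        assert state.symmetry.rise_A == pytest.approx(12.1, abs=0.15)


class TestSortingNullCase:
    def test_equal_symmetries_sort_at_chance(self, template, acq_desk):
        from helifil.simulate import simulate_mixture

        sym = HelicalSymmetry(28.1, 12.5, 5)
        sym_b = HelicalSymmetry(28.1, 12.5001, 5)  # physically unresolvable
        stk = simulate_mixture(
            template, sym, sym_b, 0.5, 120, acq_desk,
            box_px=64, voxel_A=3.0, seed=4, target_snr=0.1,
        )
        stk = phase_flip(stk, acq_desk)
        labels, _, _ = sort_segments(
            stk, sym, sym_b, n_cycles=2, seed=0, acq=acq_desk, init_iters=1
        )
        truth = stk.meta["class_label"].to_numpy()
        acc = (labels == truth).mean()
        assert 0.3 < acc < 0.7


class TestTransferAlignment:
    def test_identity_transfer_matches_direct(self, volume64, acq_desk):
        stk = simulate_segment_stack(volume64, 10, acq_desk, seed=6, rise_A=12.1, target_snr=0.5)
        az = np.round(stk.meta["azimuth_deg"].to_numpy() / 4) * 4 % 360
        n = len(stk)
        params = AlignmentParams(az, np.zeros(n), np.zeros(n), np.zeros(n), np.ones(n))
        direct = backproject(stk, params)
        transferred = transfer_alignment(params, stk)
        assert np.allclose(direct.data, transferred.data)

    def test_length_mismatch_raises(self, volume64, acq_desk):
        stk = simulate_segment_stack(volume64, 4, acq_desk, seed=6, rise_A=12.1)
        params = AlignmentParams(np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            transfer_alignment(params, stk)

    def test_high_dose_alignment_transfers_to_paired_low_dose(self, volume64, acq_desk, ped208_sym):
        """High-dose segments align more accurately than their paired
        low-dose copies; transferring those parameters therefore gives the
        low-dose reconstruction the better alignment without re-search.
        (A naive FSC-to-reference comparison would instead reward the
        low-dose self-alignment through reference-noise overfitting.)"""
        clean = simulate_segment_stack(
            volume64, 80, acq_desk, seed=7, rise_A=12.1, noise_sigma=0.0, tilt_jitter_deg=0.0
        )
        sig_var = np.mean([im.var() for im in clean.images])
        sym_vol = symmetrize(volume64, ped208_sym)
        refs = make_references(sym_vol, ped208_sym, 4.0)
        azs = clean.meta["azimuth_deg"].to_numpy()
        dzs = clean.meta["shift_z_px"].to_numpy()
        rise_px = ped208_sym.rise_A / 3.0

        def accuracy(par):
            ok = np.zeros(len(azs), dtype=bool)
            for k in (-2, -1, 0, 1, 2):  # helical (azimuth, z) degeneracy
                d_az = np.abs((par.azimuth_deg - (azs + k * ped208_sym.twist_deg) + 36) % 72 - 36)
                ok |= (d_az <= 4) & (np.abs(par.shift_z_px - (dzs + k * rise_px)) <= 1.5)
            return ok.mean()

        def with_noise(rng, snr):
            images = clean.images + rng.normal(
                scale=np.sqrt(sig_var / snr), size=clean.images.shape
            ).astype(np.float32)
            return phase_flip(SegmentStack(images, clean.meta.copy(), 3.0), acq_desk)

        hi = with_noise(np.random.default_rng(71), 0.10)  # ~20 e-/A^2 stand-in
        lo = with_noise(np.random.default_rng(72), 0.01)  # heavily dose-limited
        params_hi = align_segments(hi, refs, (4, 4))
        params_lo = align_segments(lo, refs, (4, 4))
        assert accuracy(params_hi) > accuracy(params_lo) + 0.1
        # and the transfer itself is a plain re-use of the parameters
        transferred = transfer_alignment(params_hi, lo, acq=acq_desk)
        direct = backproject(lo, params_hi, acq=acq_desk)
        assert np.allclose(transferred.data, direct.data)
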