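"""Synthetic filament generator: templates, rendering, projection, stacks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import corr
from helifil.simulate import (
    SubunitTemplate,
    make_test_subunit,
    project_volume,
    render_volume,
    simulate_mixture,
    simulate_segment_stack,
)
from helifil.symmetry import HelicalSymmetry
from helifil.volume import DensityVolume, SegmentStack
from helifil.voxel_ops import rotate_volume_z


class TestSubunitTemplate:
    def test_deterministic_for_seed(self):
        a, b = make_test_subunit(7), make_test_subunit(7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_seeds_differ(self):
        assert not np.allclose(make_test_subunit(1).positions, make_test_subunit(2).positions)

    def test_minimum_atom_count_enforced(self):
        with pytest.raises(ValueError):
            make_test_subunit(1, n_atoms=9)

    def test_no_internal_rotational_symmetry(self, template):
        # exhaustive rotation-grid oracle: best self-superposition RMSD
        # under any rotation >= 30 degrees stays above 2 A
        pts = template.positions - template.positions.mean(axis=0)
        best = np.inf
        for axis in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1], [1, -1, 0], [0, 1, 1]):
            axis = np.array(axis) / np.linalg.norm(axis)
            for ang in range(30, 331, 15):  # geodesic rotation angle >= 30 deg
                R = Rotation.from_rotvec(np.deg2rad(ang) * axis).as_matrix()
                rot = pts @ R.T
                d = np.sqrt(((rot[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
                rmsd = np.sqrt((d.min(axis=1) ** 2).mean())
                best = min(best, rmsd)
        assert best > 2.0


class TestRenderVolume:
    def test_integrated_density_matches_analytic_gaussians(self, template):
        sym = HelicalSymmetry(28.2, 12.1, 5)
        vol = render_volume(template, sym, 3, 96, 3.0)
        n_copies = 15
        analytic = n_copies * np.sum(
            template.amplitudes * (2 * np.pi) ** 1.5 * template.widths**3
        ) / 3.0**3
        assert vol.data.sum() == pytest.approx(analytic, rel=0.01)

    def test_c5_volume_invariant_under_72_degrees(self, volume64):
        assert corr(volume64.data, rotate_volume_z(volume64.data, 72.0)) > 0.99

    def test_lateral_overflow_raises(self, template):
        with pytest.raises(ValueError, match="laterally"):
            render_volume(template, HelicalSymmetry(28.2, 12.1, 5), 3, 24, 3.0)

    def test_axial_overflow_raises_without_clip(self, template):
        with pytest.raises(ValueError, match="axially"):
            render_volume(template, HelicalSymmetry(28.2, 12.1, 5), 40, 96, 3.0)


class TestProjectVolume:
    def test_linearity(self, volume64):
        a = volume64
        b = DensityVolume(a.data[::-1].copy(), a.voxel_size_A)
        sum_proj = project_volume(DensityVolume(a.data + b.data, 3.0), 25.0)
        assert np.allclose(
            sum_proj, project_volume(a, 25.0) + project_volume(b, 25.0), atol=1e-3
        )

    def test_mass_conservation(self, volume64):
        img = project_volume(volume64, 0.0)
        assert img.sum() == pytest.approx(volume64.data.sum(), rel=0.01)

    def test_volume_rotation_equals_azimuth_change(self, volume64):
        rotated = DensityVolume(rotate_volume_z(volume64.data, 33.0), 3.0)
        a = project_volume(rotated, 0.0)
        b = project_volume(volume64, 33.0)
        assert corr(a, b) > 0.999


class TestSegmentStack:
    def test_counts_and_metadata(self, volume64, acq_desk):
        stk = simulate_segment_stack(volume64, 50, acq_desk, seed=3, rise_A=12.1, noise_sigma=1.0)
        assert len(stk) == 50 and len(stk.meta) == 50

    def test_noiseless_fixed_defocus_equals_filtered_projection(self, volume64, acq_desk):
        from helifil.ctf import CtfParams, apply_ctf

        stk = simulate_segment_stack(
            volume64, 1, acq_desk, defocus_range_um=(1.5, 1.5), noise_sigma=0.0,
            seed=5, rise_A=None, tilt_jitter_deg=0.0,
        )
        m = stk.meta.iloc[0]
        proj = project_volume(volume64, m["azimuth_deg"])
        expect = apply_ctf(proj, CtfParams(m["defocus_A"]), acq_desk, 3.0)
        assert np.allclose(stk.images[0], expect, atol=1e-4)

    def test_empirical_snr_near_requested(self, volume64, acq_desk):
        target = 0.5
        noiseless = simulate_segment_stack(
            volume64, 40, acq_desk, seed=9, rise_A=12.1, noise_sigma=0.0
        )
        noisy = simulate_segment_stack(
            volume64, 40, acq_desk, seed=9, rise_A=12.1, target_snr=target
        )
        sig_var = np.mean([im.var() for im in noiseless.images])
        noise_var = np.mean([(a - b).var() for a, b in zip(noisy.images, noiseless.images)])
        assert sig_var / noise_var == pytest.approx(target, rel=0.2)

    def test_reproducible_for_seed(self, volume64, acq_desk):
        a = simulate_segment_stack(volume64, 5, acq_desk, seed=4, rise_A=12.1, target_snr=0.1)
        b = simulate_segment_stack(volume64, 5, acq_desk, seed=4, rise_A=12.1, target_snr=0.1)
        assert np.array_equal(a.images, b.images)
        assert a.meta.equals(b.meta)

    def test_negative_count_rejected(self, volume64, acq_desk):
        with pytest.raises(ValueError):
            simulate_segment_stack(volume64, -1, acq_desk)

    def test_mrc_and_metadata_round_trip(self, volume64, acq_desk, tmp_path):
        stk = simulate_segment_stack(volume64, 4, acq_desk, seed=2, rise_A=12.1, target_snr=0.2)
        stk.write(tmp_path / "s.mrc", tmp_path / "s.txt")
        back = SegmentStack.read(tmp_path / "s.mrc", tmp_path / "s.txt")
        assert np.allclose(back.images, stk.images, atol=1e-6)
        assert back.pixel_size_A == pytest.approx(3.0)
        assert np.allclose(back.meta["azimuth_deg"], stk.meta["azimuth_deg"])


class TestMixture:
    def test_stratified_counts(self, template, acq_desk):
        sym_a = HelicalSymmetry(28.1, 12.5, 5)
        sym_b = HelicalSymmetry(27.9, 13.2, 5)
        stk = simulate_mixture(
            template, sym_a, sym_b, 0.5, 40, acq_desk, box_px=64, voxel_A=3.0, seed=1,
            target_snr=0.5,
        )
        labels = stk.meta["class_label"].to_numpy()
        assert (labels == 0).sum() == 20 and (labels == 1).sum() == 20

    def test_degenerate_fraction_rejected(self, template, acq_desk):
        sym = HelicalSymmetry(28.1, 12.5, 5)
        with pytest.raises(ValueError):
            simulate_mixture(template, sym, sym, 0.0, 40, acq_desk)

    def test_default_f_pilus_rises(self):
        # the two F-pilus populations differ in axial rise: 12.5 vs 13.2 A
        a = HelicalSymmetry(28.1, 12.5, 5)
        b = HelicalSymmetry(27.9, 13.2, 5)
        assert b.rise_A - a.rise_A == pytest.approx(0.7)


def test_power_spectrum_layer_lines_at_analytic_positions(volume96, ped208_sym):
    """A noiseless projection shows the helical layer lines of the lattice:
    the dominant n=+/-5 line of the five-start family at 5/pitch, and the
    meridional line from pentamer-layer stacking at 1/rise."""
    img = project_volume(volume96, 17.0)
    axial = (np.abs(np.fft.rfft(img - img.mean(), axis=0)) ** 2).sum(axis=1)
    n = img.shape[0]
    window_A = n * 3.0
    five_start_idx = round(ped208_sym.cyclic_order * window_A / ped208_sym.pitch_A)
    rise_idx = round(window_A / ped208_sym.rise_A)
    lo = 4  # skip the low-frequency envelope
    peak = lo + int(np.argmax(axial[lo : n // 2]))
    assert abs(peak - five_start_idx) <= 1
    # 1/rise is a local maximum over its two-sample neighbourhood
    assert axial[rise_idx] > max(
        axial[rise_idx - 2], axial[rise_idx - 1], axial[rise_idx + 1], axial[rise_idx + 2]
    )


def test_template_field_validation():
    with pytest.raises(ValueError):
        SubunitTemplate(np.zeros((5, 3)), np.ones(5), np.ones(5), 0)
    with pytest.raises(ValueError):
        SubunitTemplate(np.zeros((12, 3)), np.ones(11), np.ones(12), 0)
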