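"""Parametric-map fitting: preprocessing, round trips, equivariances."""
import numpy as np
import pytest

from qmrpipe.acquisition import AcquisitionSpec, default_dwi, default_mems, default_vfa
from qmrpipe.containers import ImageStack
from qmrpipe.phantom import add_rician_noise, build_label_map, simulate_stack, vfa_signal
from qmrpipe.relaxometry import (
    compute_mtr,
    fit_adc,
    fit_r1_vfa,
    fit_r2_mems,
    preprocess,
    split_mt_pair,
)


def _stack(data, axis="none"):
    return ImageStack(data=np.asarray(data, float), voxel_size=(0.25, 0.25, 0.5), axis=axis)


class TestPreprocess:
    def test_sigma_zero_is_identity(self, rng):
        st = _stack(rng.random((8, 8, 3, 2)), axis="echo")
        out = preprocess(st, sigma=0.0)
        assert out.data is st.data

    def test_uniform_image_unchanged(self):
        st = _stack(np.full((16, 16, 3), 7.5))
        out = preprocess(st, sigma=0.75)
        assert np.allclose(out.data, 7.5, atol=1e-12)

    def test_delta_image_center_equals_kernel_peak(self):
        # oracle: explicit normalised Gaussian kernel, truncated at 4 sigma
        sigma = 0.75
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        img = np.zeros((17, 17, 1))
        img[8, 8, 0] = 1.0
        out = preprocess(_stack(img), sigma=sigma)
        assert out.data[8, 8, 0] == pytest.approx(k1[radius] ** 2, rel=1e-10)

    def test_smoothing_is_in_plane_only(self):
        img = np.zeros((9, 9, 3))
        img[4, 4, 1] = 1.0
        out = preprocess(_stack(img), sigma=1.0)
        assert out.data[..., 0].sum() == 0 and out.data[..., 2].sum() == 0


class TestVfaR1:
    def test_noiseless_single_value_round_trip(self, vfa_acq):
        truth_r1, truth_s0 = 1.0, 50.0
        sig = np.stack(
            [vfa_signal(np.full((4, 4, 1), truth_s0), truth_r1, vfa_acq.tr, a)
             for a in vfa_acq.flip_angles_deg],
            axis=-1,
        )
        m = fit_r1_vfa(_stack(sig, "flip_angle"), vfa_acq)
        assert np.allclose(m.values[m.mask], truth_r1, rtol=1e-6)

    def test_rn_phantom_roi_mean(self, rn_phantom, rn_rois, vfa_acq):
        st = simulate_stack(rn_phantom, vfa_acq)
        m = fit_r1_vfa(st, vfa_acq)
        assert m.roi_mean(rn_rois["rn"]) == pytest.approx(1.26, rel=1e-6)

    def test_requires_three_distinct_angles(self):
        spec = AcquisitionSpec(sequence="vfa", tr=0.1, flip_angles_deg=[10.0, 30.0])
        sig = np.ones((2, 2, 1, 2))
        with pytest.raises(ValueError, match="3 distinct"):
            fit_r1_vfa(_stack(sig, "flip_angle"), spec)

    def test_rician_noise_median_bias_small(self, vfa_acq, rng):
        # 1000 voxels at R1=1.08, SNR 50 on s0
        truth_r1, s0 = 1.08, 100.0
        clean = np.stack(
            [vfa_signal(np.full((1000, 1, 1), s0), truth_r1, vfa_acq.tr, a)
             for a in vfa_acq.flip_angles_deg],
            axis=-1,
        )
        noisy = add_rician_noise(clean, s0 / 50.0, rng)
        m = fit_r1_vfa(_stack(noisy, "flip_angle"), vfa_acq)
        med = np.median(m.values[m.mask])
        assert abs(med - truth_r1) / truth_r1 < 0.02

    def test_scale_equivariance(self, rn_phantom, rn_rois, vfa_acq):
        st = simulate_stack(rn_phantom, vfa_acq)
        scaled = _stack(st.data * 37.0, "flip_angle")
        a = fit_r1_vfa(st, vfa_acq)
        b = fit_r1_vfa(scaled, vfa_acq)
        assert b.roi_mean(rn_rois["rn"]) == pytest.approx(a.roi_mean(rn_rois["rn"]), rel=1e-8)


class TestMemsR2:
    def test_noiseless_recovery_with_zero_constant(self, mems_acq):
        truth_r2 = 17.6
        sig = 80.0 * np.exp(-mems_acq.te_list * truth_r2)
        data = np.broadcast_to(sig, (3, 3, 1, 16)).copy()
        m = fit_r2_mems(_stack(data, "echo"), mems_acq)
        assert np.allclose(m.values[m.mask], truth_r2, rtol=1e-6)

    def test_constant_offset_recovered_and_two_param_biased(self, mems_acq):
        # truth with an additive offset of 0.1 S(0): the 3-parameter fit is
        # exact while a 2-parameter log-linear fit underestimates R2
        truth_r2, s0 = 14.9, 100.0
        te = mems_acq.te_list
        sig = s0 * np.exp(-te * truth_r2) + 0.1 * s0
        data = np.broadcast_to(sig, (2, 2, 1, 16)).copy()
        m = fit_r2_mems(_stack(data, "echo"), mems_acq)
        assert np.allclose(m.values[m.mask], truth_r2, rtol=1e-6)
        slope = np.polyfit(te, np.log(sig), 1)[0]
        assert -slope < 0.8 * truth_r2  # 2-parameter fit biased low

    def test_constant_signal_flagged_degenerate(self, mems_acq):
        data = np.full((2, 2, 1, 16), 42.0)
        m = fit_r2_mems(_stack(data, "echo"), mems_acq)
        degen = m.meta["degenerate_mask"]
        fitted = m.values[m.mask]
        # either a ~zero decay rate or ~zero decay amplitude, flagged
        assert degen[m.mask].all()
        assert np.all((fitted < 0.1) | np.isclose(fitted, 0, atol=0.1)) or m.report[
            "n_flagged_degenerate"
        ] == int(m.mask.sum())

    def test_requires_four_echoes(self):
        spec = AcquisitionSpec(sequence="mems", tr=6.0, te_list=[0.01, 0.02, 0.03])
        with pytest.raises(ValueError, match="4 echoes"):
            fit_r2_mems(_stack(np.ones((2, 2, 1, 3)), "echo"), spec)


class TestAdc:
    def test_isotropic_round_trip(self, dwi_acq):
        d = 0.7  # um^2/ms
        b = dwi_acq.b_matrices
        expo = 1e-3 * np.einsum("vij,ij->v", b, d * np.eye(3))
        sig = 90.0 * np.exp(-expo)
        data = np.broadcast_to(sig, (3, 3, 1, len(b))).copy()
        m = fit_adc(_stack(data, "diffusion"), dwi_acq)
        assert np.allclose(m.values[m.mask], 0.700, rtol=1e-6)

    def test_anisotropic_trace_third(self, dwi_acq):
        dten = np.diag([1.0, 0.5, 0.3])
        b = dwi_acq.b_matrices
        expo = 1e-3 * np.einsum("vij,ij->v", b, dten)
        sig = 100.0 * np.exp(-expo)
        data = np.broadcast_to(sig, (2, 2, 1, len(b))).copy()
        m = fit_adc(_stack(data, "diffusion"), dwi_acq)
        assert np.allclose(m.values[m.mask], 0.600, rtol=1e-6)

    def test_tumor_phantom_roi_mean(self, tumor_phantom, tumor_rois, dwi_acq):
        st = simulate_stack(tumor_phantom, dwi_acq)
        m = fit_adc(st, dwi_acq)
        assert m.roi_mean(tumor_rois["tumor"]) == pytest.approx(0.833, rel=1e-6)

    def test_rank_deficient_encoding_rejected(self):
        # all gradients along x: cannot resolve the tensor
        g = np.array([1.0, 0.0, 0.0])
        mats = np.stack([np.zeros((3, 3))] + [1000 * np.outer(g, g)] * 6)
        spec = AcquisitionSpec(sequence="dwi", tr=1.5, b_matrices=mats)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_adc(_stack(np.ones((2, 2, 1, 7)), "diffusion"), spec)


class TestMtr:
    def test_identical_pair_gives_zero(self):
        off = _stack(np.full((4, 4, 2), 100.0))
        m = compute_mtr(off, off)
        assert np.allclose(m.values[m.mask], 0.0, atol=1e-12)

    def test_printed_arithmetic(self):
        off = _stack(np.full((4, 4, 1), 100.0))
        on = _stack(np.full((4, 4, 1), 75.9))
        m = compute_mtr(on, off)
        assert np.allclose(m.values[m.mask], 24.1, atol=1e-10)

    def test_full_transfer_gives_hundred(self):
        off = _stack(np.full((4, 4, 1), 100.0))
        on = _stack(np.zeros((4, 4, 1)))
        m = compute_mtr(on, off)
        assert np.allclose(m.values[m.mask], 100.0, atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_mtr(_stack(np.ones((4, 4, 1))), _stack(np.ones((5, 4, 1))))

    def test_invariant_under_smoothing_of_uniform_pair(self, mt_acq):
        p = build_label_map(lesion_layout="tumor", matrix=(64, 64), n_slices=5)
        st = simulate_stack(p, mt_acq)
        on, off = split_mt_pair(st)
        raw = compute_mtr(on, off)
        sm = preprocess(st, 0.75)
        on_s, off_s = split_mt_pair(sm)
        smooth = compute_mtr(on_s, off_s)
        # deep inside each uniform tissue the ratio is untouched by smoothing
        from qmrpipe.phantom import roi_masks

        roi = roi_masks(p, erosion=3)["tumor"]
        assert smooth.roi_mean(roi) == pytest.approx(raw.roi_mean(roi), abs=1e-9)


def test_uncertainty_shrinks_with_signal_averaging(vfa_acq, rng):
    """Averaging N acquisitions shrinks fitted R1 scatter by ~sqrt(N)."""
    s0, r1 = 100.0, 1.0
    clean = np.stack(
        [vfa_signal(np.full((400, 1, 1), s0), r1, vfa_acq.tr, a)
         for a in vfa_acq.flip_angles_deg],
        axis=-1,
    )
    sd = s0 / 50.0

    def fitted_scatter(n_avg):
        avg = np.mean(
            [add_rician_noise(clean, sd, rng) for _ in range(n_avg)], axis=0
        )
        m = fit_r1_vfa(_stack(avg, "flip_angle"), vfa_acq)
        return m.values[m.mask].std(ddof=1)

    ratio = fitted_scatter(1) / fitted_scatter(4)
    assert ratio == pytest.approx(2.0, rel=0.25)


@pytest.mark.parametrize("scale", [0.5, 3.0])
def test_all_fits_scale_equivariant(tumor_phantom, tumor_rois, scale):
    """Multiplying the raw stacks by c>0 leaves R2/ADC/MTR untouched."""
    mems, dwi = default_mems(), default_dwi()
    roi = tumor_rois["tumor"]
    st2 = simulate_stack(tumor_phantom, mems)
    st3 = simulate_stack(tumor_phantom, dwi)
    r2_a = fit_r2_mems(st2, mems).roi_mean(roi)
    r2_b = fit_r2_mems(
        ImageStack(data=st2.data * scale, voxel_size=st2.voxel_size, axis="echo"), mems
    ).roi_mean(roi)
    adc_a = fit_adc(st3, dwi).roi_mean(roi)
    adc_b = fit_adc(
        ImageStack(data=st3.data * scale, voxel_size=st3.voxel_size, axis="diffusion"), dwi
    ).roi_mean(roi)
    assert r2_b == pytest.approx(r2_a, rel=1e-8)
    assert adc_b == pytest.approx(adc_a, rel=1e-10)
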