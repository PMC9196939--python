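"""Forward-simulation correctness: label maps, signal models, noise models."""
import numpy as np
import pytest

from qmrpipe.acquisition import AcquisitionSpec, six_direction_bmatrices
from qmrpipe.containers import ImageStack
from qmrpipe.phantom import (
    LABELS,
    add_rician_noise,
    build_label_map,
    simulate_fid_series,
    simulate_stack,
    simulate_titration,
    vfa_signal,
)
from qmrpipe.presets import (
    C_NA_MM,
    CHEMICAL_SHIFTS_PPM,
    DMRS_F0_MHZ,
    KineticCurve,
    cohort_kinetics,
    study_defaults,
)


class TestLabelMap:
    def test_control_layout_has_no_lesion_labels(self, small_geometry):
        p = build_label_map(lesion_layout="control", **small_geometry)
        labels = set(np.unique(p.label_map))
        assert LABELS["tumor"] not in labels and LABELS["rn"] not in labels
        assert {LABELS["cortex"], LABELS["muscle"], LABELS["background"]} <= labels

    def test_mixed_layout_has_disjoint_tumor_and_rn(self, small_geometry):
        p = build_label_map(lesion_layout="mixed", **small_geometry)
        tumor = p.mask("tumor")
        rn = p.mask("rn")
        assert tumor.any() and rn.any()
        assert not (tumor & rn).any()

    def test_label_map_is_deterministic(self, small_geometry):
        a = build_label_map(lesion_layout="mixed", seed=1, **small_geometry)
        b = build_label_map(lesion_layout="mixed", seed=1, **small_geometry)
        assert np.array_equal(a.label_map, b.label_map)

    def test_unknown_layout_names_valid_tags(self):
        with pytest.raises(ValueError, match="tumor.*rn.*mixed.*control"):
            build_label_map(lesion_layout="cyst")

    def test_mixed_lesions_use_admixed_presets(self, small_geometry):
        p = build_label_map(lesion_layout="mixed", **small_geometry)
        assert p.presets[LABELS["tumor"]].name == "tumor_in_mixed"
        assert p.presets[LABELS["rn"]].name == "rn_in_mixed"


class TestImagingForwardModels:
    def test_vfa_signal_matches_closed_form(self):
        # single voxel, R1=1.0 s^-1, TR=0.1 s, s0=1, theta=30 deg
        expected = (1 - np.exp(-0.1)) * np.sin(np.deg2rad(30)) / (
            1 - np.exp(-0.1) * np.cos(np.deg2rad(30))
        )
        got = vfa_signal(np.array(1.0), np.array(1.0), 0.1, 30.0)
        assert got == pytest.approx(expected, abs=1e-15)

    def test_mt_pair_ratio_equals_preset_mtr(self, tumor_phantom, mt_acq):
        st = simulate_stack(tumor_phantom, mt_acq)
        off = st.data[..., 0]
        on = st.data[..., 1]
        lesion = tumor_phantom.mask("tumor")
        ratio = (off[lesion] - on[lesion]) / off[lesion]
        assert np.allclose(ratio, 0.241, atol=1e-12)

    def test_dwi_all_b_zero_reproduces_s0_everywhere(self, tumor_phantom):
        spec = AcquisitionSpec(
            sequence="dwi", tr=1.5, b_matrices=np.zeros((7, 3, 3))
        )
        st = simulate_stack(tumor_phantom, spec)
        s0 = tumor_phantom.param_volume(lambda p: p.s0)
        for v in range(st.n_volumes):
            assert np.array_equal(st.data[..., v], s0)

    def test_noiseless_simulation_is_deterministic(self, tumor_phantom, vfa_acq):
        a = simulate_stack(tumor_phantom, vfa_acq)
        b = simulate_stack(tumor_phantom, vfa_acq)
        assert np.array_equal(a.data, b.data)

    def test_noisy_simulation_reproducible_by_seed(self, small_geometry, vfa_acq):
        mk = lambda s: build_label_map(
            lesion_layout="tumor", noise="rician", noise_sd=0.02, seed=s, **small_geometry
        )
        a = simulate_stack(mk(5), vfa_acq)
        b = simulate_stack(mk(5), vfa_acq)
        c = simulate_stack(mk(6), vfa_acq)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_missing_dce_curve_names_preset_and_field(self, small_geometry):
        presets = study_defaults()
        presets["cortex"].dce_curve = None
        p = build_label_map(lesion_layout="control", presets=presets, **small_geometry)
        spec = AcquisitionSpec(sequence="dce", tr=0.047, n_frames=10, frame_dt=3.0)
        with pytest.raises(ValueError, match="cortex.*dce_curve"):
            simulate_stack(p, spec)


class TestRicianNoise:
    def test_zero_signal_mean_is_rayleigh(self, rng):
        # at s0=0 the magnitude mean is sd*sqrt(pi/2)
        sd = 3.0
        draws = add_rician_noise(np.zeros(200_000), sd, rng)
        assert draws.mean() == pytest.approx(sd * np.sqrt(np.pi / 2), rel=0.02)

    def test_high_snr_bias_vanishes(self, rng):
        sd = 1.0
        s = 500.0  # SNR 500
        draws = add_rician_noise(np.full(100_000, s), sd, rng)
        assert abs(draws.mean() - s) / s < 1e-4

    def test_empirical_sd_matches_configured(self, rng):
        sd = 2.0
        s = 200.0
        draws = add_rician_noise(np.full(50_000, s), sd, rng)
        assert draws.std() == pytest.approx(sd, rel=0.1)


class TestFidSeries:
    def test_pre_infusion_blocks_contain_only_hod(self, dmrs_acq):
        kin = cohort_kinetics("control")
        fids = simulate_fid_series(kin, dmrs_acq, n_blocks=4, seed=0)
        amps = np.array(fids.meta["true_amplitudes"])
        names = fids.meta["resonances"]
        for j, name in enumerate(names):
            if name == "HOD":
                assert amps[0, j] > 0 and amps[1, j] > 0
            else:
                assert amps[0, j] == 0 and amps[1, j] == 0

    def test_fft_peak_at_configured_shift(self, dmrs_acq):
        # single-resonance series: spectral peak within one bin of truth
        kin = cohort_kinetics("tumor")
        lac_hz = (CHEMICAL_SHIFTS_PPM["Lac"] - CHEMICAL_SHIFTS_PPM["HOD"]) * DMRS_F0_MHZ
        only_lac = {
            "HOD": KineticCurve(baseline=C_NA_MM, plateau=C_NA_MM, rate=0.1),
            "Glc": KineticCurve(baseline=0.0, plateau=0.0, rate=0.1),
            "Glx": KineticCurve(baseline=0.0, plateau=0.1, rate=0.1),
            "Lac": KineticCurve(baseline=0.0, plateau=50.0, rate=0.5),
        }
        import dataclasses

        kin = dataclasses.replace(kin, curves=only_lac)
        fids = simulate_fid_series(kin, dmrs_acq, n_blocks=12, seed=0)
        spec = np.fft.fft(fids.data[-1] - fids.data[0])  # difference isolates Lac+Glx growth
        freqs = np.fft.fftfreq(fids.n_points, fids.dwell)
        peak = freqs[np.argmax(np.abs(spec))]
        bin_hz = 1.0 / (fids.n_points * fids.dwell)
        assert abs(peak - lac_hz) <= bin_hz

    def test_amplitudes_linear_in_concentration(self, dmrs_acq):
        kin1 = cohort_kinetics("tumor")
        curves2 = {
            n: KineticCurve(
                baseline=c.baseline * 2, plateau=c.plateau * 2, rate=c.rate, onset=c.onset
            )
            for n, c in kin1.curves.items()
        }
        import dataclasses

        kin2 = dataclasses.replace(kin1, curves=curves2, c_na=2 * kin1.c_na)
        a1 = simulate_fid_series(kin1, dmrs_acq, n_blocks=5, seed=0).data
        a2 = simulate_fid_series(kin2, dmrs_acq, n_blocks=5, seed=0).data
        assert np.allclose(a2, 2 * a1, rtol=1e-12)

    def test_too_few_blocks_rejected(self, dmrs_acq):
        with pytest.raises(ValueError, match="3 blocks"):
            simulate_fid_series(cohort_kinetics("control"), dmrs_acq, n_blocks=2)


class TestTitration:
    def test_noiseless_amplitude_arithmetic(self):
        s = simulate_titration(delta_hod_mM=(0.0, 36.0), c_na=16.35, gain=1.0)
        assert s.amplitudes[1] == pytest.approx(52.35, abs=1e-12)
        assert s.amplitudes[0] == pytest.approx(16.35, abs=1e-12)

    def test_default_series_has_six_samples(self):
        s = simulate_titration()
        assert len(s.deltas) == 6
        assert set(s.deltas) == {0.0, 36.0, 72.0, 108.0, 144.0, 180.0}

    def test_gain_scales_amplitudes(self):
        a = simulate_titration(gain=1.0).amplitudes
        b = simulate_titration(gain=2.5).amplitudes
        assert np.allclose(b, 2.5 * a)


def test_six_direction_scheme_spans_tensor_space():
    mats = six_direction_bmatrices(1000.0)
    rows = []
    for b in mats:
        rows.append([b[0, 0], b[1, 1], b[2, 2], 2 * b[0, 1], 2 * b[0, 2], 2 * b[1, 2]])
    assert np.linalg.matrix_rank(np.array(rows)) == 6
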