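"""Time-domain spectral fitting and absolute quantification."""
import dataclasses

import numpy as np
import pytest
from scipy.optimize import least_squares

from qmrpipe.acquisition import default_dmrs
from qmrpipe.containers import FIDSeries, TitrationSeries
from qmrpipe.dmrs import (
    SpectralModel,
    correct_amplitudes,
    fit_fid_series,
    glucose_dose_moles,
    glx_lac_timecourse,
    ppm_to_concentration,
    standard_addition,
    to_concentrations,
)
from qmrpipe.phantom import simulate_fid_series, simulate_titration
from qmrpipe.presets import (
    C_NA_MM,
    CHEMICAL_SHIFTS_PPM,
    DMRS_F0_MHZ,
    KineticCurve,
    QuantConfig,
    cohort_kinetics,
)


def _fid(amps, freqs, r2s, dwell=1 / 1500, n=1024, phase=0.0, noise_sd=0.0, seed=0):
    """Hand-built FID series: amps is (blocks, K)."""
    amps = np.atleast_2d(np.asarray(amps, float))
    t = np.arange(n) * dwell
    basis = np.exp((1j * 2 * np.pi * np.asarray(freqs)[None, :] - np.asarray(r2s)[None, :]) * t[:, None])
    data = np.exp(1j * phase) * (amps @ basis.T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape))
    return FIDSeries(
        data=data, dwell=dwell, f0_mhz=DMRS_F0_MHZ, ppm_ref=4.8,
        block_times=np.arange(amps.shape[0]) * 10.0,
        meta={"block_duration_min": 10.0},
    )


def _init(names, freqs, r2s, n_blocks):
    return SpectralModel(
        resonances=list(names),
        frequencies_hz=np.asarray(freqs, float),
        r2star=np.asarray(r2s, float),
        amplitudes=np.ones((n_blocks, len(names))),
    )


class TestFidFit:
    def test_single_damped_sinusoid_exact_recovery(self):
        fids = _fid([[1.0]], [50.0], [30.0])
        model = fit_fid_series(fids, _init(["X"], [55.0], [20.0], 1))
        assert model.amplitudes[0, 0] == pytest.approx(1.0, rel=1e-8)
        assert model.frequencies_hz[0] == pytest.approx(50.0, abs=1e-6)
        assert model.r2star[0] == pytest.approx(30.0, rel=1e-8)

    def test_four_resonance_series_matches_generator(self, dmrs_acq):
        kin = cohort_kinetics("tumor")
        fids = simulate_fid_series(kin, dmrs_acq, n_blocks=8, seed=0)
        names = fids.meta["resonances"]
        init = _init(names, np.array(fids.meta["true_frequencies_hz"]) + 3.0, [20.0] * 4, 8)
        model = fit_fid_series(fids, init)
        truth = np.array(fids.meta["true_amplitudes"])
        assert np.abs(model.amplitudes - truth).max() <= 1e-6 * truth.max()

    def test_global_phase_recovered(self):
        fids = _fid([[2.0, 1.0]], [-80.0, 120.0], [25.0, 35.0], phase=0.7)
        model = fit_fid_series(fids, _init(["A", "B"], [-75.0, 115.0], [20.0, 20.0], 1))
        assert model.phase == pytest.approx(0.7, abs=1e-6)
        assert model.amplitudes[0] == pytest.approx([2.0, 1.0], rel=1e-7)

    def test_varpro_matches_brute_force_nls(self):
        """Variable projection agrees with a fully free nonlinear fit."""
        freqs, r2s = [-60.0, 90.0], [20.0, 40.0]
        amps = [[1.5, 0.7], [1.1, 0.9], [0.6, 1.3]]
        fids = _fid(amps, freqs, r2s, noise_sd=0.01, seed=3)
        model = fit_fid_series(fids, _init(["A", "B"], [-55.0, 85.0], [25.0, 25.0], 3))

        t = fids.time_axis
        d = np.concatenate([fids.data.real, fids.data.imag], axis=1).ravel()

        def full_resid(x):
            f, r, ph = x[:2], x[2:4], x[4]
            a = x[5:].reshape(3, 2)
            basis = np.exp(1j * ph) * np.exp((1j * 2 * np.pi * f[None] - r[None]) * t[:, None])
            m = a @ basis.T
            return np.concatenate([m.real, m.imag], axis=1).ravel() - d

        x0 = np.concatenate([[-55.0, 85.0, 25.0, 25.0, 0.0], np.ones(6)])
        sol = least_squares(full_resid, x0, method="lm", max_nfev=20000)
        assert model.frequencies_hz == pytest.approx(sol.x[:2], abs=1e-6)
        assert model.r2star == pytest.approx(sol.x[2:4], rel=1e-6)
        assert model.amplitudes.ravel() == pytest.approx(sol.x[5:], rel=1e-6)

    def test_amplitude_sd_calibrated_by_monte_carlo(self):
        """Covariance SDs track the empirical scatter of repeated fits."""
        sd = 0.05
        est_amp, est_sd = [], []
        for seed in range(200):
            fids = _fid([[3.0]], [40.0], [30.0], n=256, noise_sd=sd, seed=seed)
            m = fit_fid_series(fids, _init(["X"], [43.0], [25.0], 1))
            est_amp.append(m.amplitudes[0, 0])
            est_sd.append(m.amplitude_sd[0, 0])
        mc_sd = np.std(est_amp, ddof=1)
        assert np.mean(est_sd) == pytest.approx(mc_sd, rel=0.2)

    def test_bootstrap_sd_agrees_with_laplace(self):
        from qmrpipe.dmrs import bootstrap_amplitude_sd

        fids = _fid([[3.0]], [40.0], [30.0], n=256, noise_sd=0.05, seed=1)
        model = fit_fid_series(fids, _init(["X"], [43.0], [25.0], 1))
        boot_sd = bootstrap_amplitude_sd(fids, model, n_boot=60, seed=2)
        assert boot_sd[0, 0] == pytest.approx(model.amplitude_sd[0, 0], rel=0.35)

    def test_near_degenerate_frequencies_warn(self):
        fids = _fid([[1.0, 1.0]], [50.0, 52.0], [30.0, 30.0])
        with pytest.warns(RuntimeWarning, match="near-degenerate"):
            fit_fid_series(fids, _init(["A", "B"], [49.0, 53.0], [30.0, 30.0], 1))

    def test_out_of_bandwidth_init_rejected(self):
        fids = _fid([[1.0]], [50.0], [30.0])
        with pytest.raises(ValueError, match="bandwidth"):
            fit_fid_series(fids, _init(["X"], [2000.0], [30.0], 1))


class TestCorrections:
    def test_no_correction_limit(self):
        cfg = QuantConfig(
            stoichiometry={"X": 1.0}, relaxation={"X": (1e-6, 1.0)}, tr=10.0, te=0.0
        )
        model = SpectralModel(["X"], [0.0], [30.0], [[5.0]])
        out = correct_amplitudes(model, cfg)
        assert out.amplitudes[0, 0] == pytest.approx(5.0, rel=1e-12)

    def test_lactate_stoichiometry_from_label_loss(self):
        cfg = QuantConfig()
        assert cfg.stoichiometry["Lac"] == pytest.approx(2 * (1 - 0.15))
        assert cfg.stoichiometry["Glx"] == pytest.approx(2 * (1 - 0.40))

    def test_factor_formula_matches_stepwise(self):
        cfg = QuantConfig(relaxation={"X": (0.3, 0.03)}, stoichiometry={"X": 1.0})
        stepwise = 1.0
        stepwise *= 1.0  # stoichiometry
        stepwise *= 1.0 - np.exp(-0.45 / 0.3)  # saturation over TR
        stepwise *= np.exp(-0.00427 / 0.03)  # echo-time decay
        assert cfg.correction_factor("X") == pytest.approx(stepwise, abs=1e-12)

    def test_missing_resonance_named(self):
        cfg = QuantConfig()
        model = SpectralModel(["Unknown"], [0.0], [30.0], [[1.0]])
        with pytest.raises(KeyError, match="Unknown"):
            correct_amplitudes(model, cfg)


class TestConcentrations:
    def _model(self, amps, names=("HOD", "Lac"), corrected=True):
        m = SpectralModel(
            list(names),
            np.zeros(len(names)),
            np.full(len(names), 30.0),
            np.atleast_2d(np.asarray(amps, float)),
            meta={"corrected": corrected, "block_times_min": list(range(len(np.atleast_2d(amps))))},
        )
        return m

    def test_pre_block_hod_is_reference_concentration(self):
        tc = to_concentrations(self._model([[4.0, 0.0], [4.0, 0.0]]), QuantConfig(), (0, 1))
        hod, _ = tc.series("HOD")
        assert np.allclose(hod, C_NA_MM)

    def test_zero_amplitude_is_zero_mM(self):
        tc = to_concentrations(self._model([[4.0, 0.0]]), QuantConfig(), (0,))
        lac, _ = tc.series("Lac")
        assert lac[0] == 0.0

    def test_corrected_equality_gives_cna_uncorrected_gives_divided(self):
        # equal corrected amplitudes -> both at c_na
        tc = to_concentrations(self._model([[4.0, 4.0]]), QuantConfig(), (0,))
        assert tc.series("Lac")[0][0] == pytest.approx(C_NA_MM, rel=1e-12)
        # equal raw amplitudes run through a stoichiometry-only correction:
        # Lac is divided by 1.7
        cfg = QuantConfig(relaxation={"HOD": (1e-9, 1e9), "Lac": (1e-9, 1e9)})
        raw = self._model([[4.0, 4.0]], corrected=False)
        tc2 = to_concentrations(raw, cfg, (0,))
        assert tc2.series("Lac")[0][0] == pytest.approx(16.35 / 1.7, rel=1e-9)
        assert tc2.series("Lac")[0][0] == pytest.approx(9.62, abs=0.01)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            to_concentrations(self._model([[0.0, 1.0]]), QuantConfig(), (0,))

    def test_negative_estimates_floored_but_raw_kept(self):
        tc = to_concentrations(self._model([[4.0, -0.5]]), QuantConfig(), (0,))
        assert tc.concentrations[0, 1] == 0.0
        assert tc.raw[0, 1] < 0.0


class TestStandardAddition:
    def test_noiseless_titration_exact(self):
        series = simulate_titration(c_na=16.35, gain=2.7)
        c_hat, se = standard_addition(series)
        assert c_hat == pytest.approx(16.35, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-6)

    def test_zero_intercept_gives_zero(self):
        series = TitrationSeries(
            deltas=np.array([0.0, 40.0, 80.0]), amplitudes=np.array([0.0, 40.0, 80.0])
        )
        c_hat, _ = standard_addition(series)
        assert c_hat == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_gain_rejected(self):
        series = TitrationSeries(
            deltas=np.array([0.0, 40.0, 80.0]), amplitudes=np.array([10.0, 8.0, 6.0])
        )
        with pytest.raises(ValueError, match="gain"):
            standard_addition(series)

    def test_monte_carlo_unbiased_within_se(self):
        truth = 16.35
        estimates, ses = [], []
        for seed in range(500):
            s = simulate_titration(c_na=truth, gain=1.0, noise_sd=0.01 * 196.35, seed=seed)
            c_hat, se = standard_addition(s)
            estimates.append(c_hat)
            ses.append(se)
        mean_est = np.mean(estimates)
        se_of_mean = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean_est - truth) < 2 * max(se_of_mean, np.mean(ses) / np.sqrt(500))


class TestPpmConversion:
    @pytest.mark.parametrize(
        "ppm,expected", [(145.9, 16.21), (148.3, 16.47), (0.0, 0.0)]
    )
    def test_printed_values(self, ppm, expected):
        assert ppm_to_concentration(ppm) == pytest.approx(expected, abs=0.01)

    def test_midrange_average(self):
        mean = (ppm_to_concentration(145.9) + ppm_to_concentration(148.3)) / 2
        assert mean == pytest.approx(16.34, abs=0.01)


class TestGlxLacRatio:
    def test_equal_concentrations_give_unity(self):
        tc = to_concentrations(
            SpectralModel(
                ["HOD", "Glx", "Lac"], np.zeros(3), np.full(3, 30.0),
                [[4.0, 2.0, 2.0], [4.0, 3.0, 3.0]],
                amplitude_sd=np.full((2, 3), 1e-3),
                meta={"corrected": True, "block_times_min": [0, 1]},
            ),
            QuantConfig(), (0,),
        )
        ratio, _, undef = glx_lac_timecourse(tc)
        assert np.allclose(ratio[~undef], 1.0)

    def test_cohort_ordering_from_generator(self, dmrs_acq):
        out = {}
        for cohort in ("tumor", "control"):
            kin = cohort_kinetics(cohort)
            fids = simulate_fid_series(kin, dmrs_acq, n_blocks=9, seed=1)
            names = fids.meta["resonances"]
            init = _init(names, fids.meta["true_frequencies_hz"], [20.0] * 4, 9)
            model = fit_fid_series(fids, init)
            tc = to_concentrations(model, QuantConfig(), (0, 1))
            ratio, _, _ = glx_lac_timecourse(tc)
            out[cohort] = ratio[-1]
        assert out["tumor"] < 1.0 < out["control"]

    def test_scale_invariance(self):
        base = np.array([[4.0, 2.0, 1.0]])
        cfg = QuantConfig()
        mk = lambda s: to_concentrations(
            SpectralModel(
                ["HOD", "Glx", "Lac"], np.zeros(3), np.full(3, 30.0), s * base,
                amplitude_sd=np.full((1, 3), 1e-4 * s),
                meta={"corrected": True, "block_times_min": [0]},
            ),
            cfg, (0,),
        )
        r1, _, _ = glx_lac_timecourse(mk(1.0))
        r2, _, _ = glx_lac_timecourse(mk(5.0))
        assert r1[0] == pytest.approx(r2[0], rel=1e-12)

    def test_lac_consistent_with_zero_flagged(self):
        tc = to_concentrations(
            SpectralModel(
                ["HOD", "Glx", "Lac"], np.zeros(3), np.full(3, 30.0),
                [[4.0, 1.0, 0.01]],
                amplitude_sd=np.array([[0.01, 0.01, 0.05]]),
                meta={"corrected": True, "block_times_min": [0]},
            ),
            QuantConfig(), (0,),
        )
        ratio, _, undef = glx_lac_timecourse(tc)
        assert undef[0] and np.isnan(ratio[0])


class TestRoundTripInvariants:
    def test_inverse_crime_recovers_kinetics_within_one_percent(self, dmrs_acq):
        kin = cohort_kinetics("rn")
        fids = simulate_fid_series(kin, dmrs_acq, n_blocks=9, seed=0)
        names = fids.meta["resonances"]
        init = _init(names, np.array(fids.meta["true_frequencies_hz"]) + 2.0, [22.0] * 4, 9)
        model = fit_fid_series(fids, init)
        tc = to_concentrations(model, QuantConfig(), (0, 1))
        mids = fids.block_times + 5.0
        for name in names:
            truth = np.asarray(kin.curves[name](mids))
            got, _ = tc.series(name)
            scale = max(truth.max(), 1e-9)
            assert np.abs(got - truth).max() <= 1e-2 * scale

    def test_gain_and_phase_invariance(self, dmrs_acq):
        kin = cohort_kinetics("control")
        ref = simulate_fid_series(kin, dmrs_acq, n_blocks=6, seed=0)
        alt = simulate_fid_series(kin, dmrs_acq, n_blocks=6, seed=0, gain=11.0, phase=0.9)
        names = ref.meta["resonances"]
        init = _init(names, ref.meta["true_frequencies_hz"], [20.0] * 4, 6)
        tc_ref = to_concentrations(fit_fid_series(ref, init), QuantConfig(), (0, 1))
        tc_alt = to_concentrations(fit_fid_series(alt, init), QuantConfig(), (0, 1))
        assert np.allclose(tc_ref.concentrations, tc_alt.concentrations, rtol=1e-6, atol=1e-9)


def test_glucose_dose_arithmetic():
    # 36 mg of the dideuterated tracer is 2e-4 mol to the printed precision
    assert glucose_dose_moles(36.0) == pytest.approx(2e-4, rel=0.02)
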