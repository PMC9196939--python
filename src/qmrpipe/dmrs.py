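"""Deuterium MRS quantification: time-domain fitting and absolute scaling.

The block-wise 2H FID series is modelled as a sum of exponentially decaying
sinusoids.  Frequencies, decay rates (R2*) and a global zero-order phase
are shared across all blocks of a time course; amplitudes are free per
block.  The fit is a separable (variable-projection) nonlinear least
squares: at each step of the nonlinear optimisation over the shared
parameters, the per-block amplitudes are solved exactly by linear least
squares.  Parameter SDs come from the covariance at the optimum (a Laplace
approximation to the posterior SDs).

Fitted amplitudes become absolute concentrations in three steps: division
by the labeling stoichiometry and relaxation attenuation, scaling by the
natural-abundance HOD internal reference acquired before glucose
administration, and (for reporting) flooring of negative point estimates.
The standard-addition estimator and the 2H mole-fraction -> mM conversion
close the calibration loop for the reference concentration itself.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from .containers import FIDSeries, TitrationSeries
from .presets import GLC_66D2_MOLAR_MASS, QuantConfig, WATER_EQUIV_PROTON_M


@dataclass
class SpectralModel:
    """A fitted (or initial) spectral model for one FID time course.

    ``frequencies_hz`` and ``r2star`` are single-valued per resonance across
    the whole time course; ``amplitudes`` has one row per block.  SD fields
    are zero-filled until a fit populates them.
    """

    resonances: list[str]
    frequencies_hz: np.ndarray
    r2star: np.ndarray  # s^-1
    amplitudes: np.ndarray  # (n_blocks, n_resonances)
    phase: float = 0.0  # radians, global zero-order
    amplitude_sd: np.ndarray | None = None
    frequency_sd: np.ndarray | None = None
    r2star_sd: np.ndarray | None = None
    phase_sd: float = 0.0
    residual_power: np.ndarray | None = None  # per block
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies_hz = np.atleast_1d(np.asarray(self.frequencies_hz, dtype=float))
        self.r2star = np.atleast_1d(np.asarray(self.r2star, dtype=float))
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        k = len(self.resonances)
        if not (len(self.frequencies_hz) == len(self.r2star) == self.amplitudes.shape[1] == k):
            raise ValueError("resonance count mismatch across model fields")
        if np.any(self.r2star <= 0):
            raise ValueError("decay rates must be positive")

    @property
    def n_blocks(self) -> int:
        return self.amplitudes.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.resonances.index(name)
        except ValueError:
            raise KeyError(f"resonance {name!r} not in model {self.resonances}") from None


@dataclass
class MetaboliteTimeCourse:
    """Per-block absolute concentrations and their uncertainties.

    ``concentrations`` is floored at zero for reporting; ``raw`` keeps the
    signed point estimates (negative excursions are informative noise).
    """

    resonances: list[str]
    times_min: np.ndarray  # block start times
    concentrations: np.ndarray  # (n_blocks, n_resonances), mM, floored
    raw: np.ndarray  # unfloored point estimates
    sd: np.ndarray  # propagated 1-sigma, mM
    meta: dict[str, Any] = field(default_factory=dict)

    def series(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.resonances.index(name)
        return self.concentrations[:, j], self.sd[:, j]


# ---------------------------------------------------------------------------
# variable-projection fit
# ---------------------------------------------------------------------------


def _real_stack(z: np.ndarray) -> np.ndarray:
    return np.concatenate([z.real, z.imag], axis=0)


def _basis(t: np.ndarray, freqs: np.ndarray, r2s: np.ndarray, phase: float) -> np.ndarray:
    """Complex model basis, one column per resonance, including the phase."""
    return np.exp(1j * phase) * np.exp(
        (1j * 2.0 * np.pi * freqs[None, :] - r2s[None, :]) * t[:, None]
    )


def _solve_amplitudes(breal: np.ndarray, dreal: np.ndarray) -> np.ndarray:
    """Exact linear solve for per-block amplitudes: (K x B)."""
    gram = breal.T @ breal
    rhs = breal.T @ dreal
    try:
        return np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(gram) @ rhs


def fit_fid_series(
    fids: FIDSeries,
    init: SpectralModel,
    max_nfev: int = 400,
) -> SpectralModel:
    """Joint variable-projection fit of a block-wise FID series.

    Shared parameters: one frequency and R2* per resonance plus a global
    zero-order phase.  Per-block real amplitudes are projected out exactly
    at every nonlinear step.  SDs for all parameters (including amplitudes)
    come from the full covariance at the optimum.
    """
    if fids.n_blocks < 1:
        raise ValueError("FID series has no blocks")
    k = len(init.resonances)
    if k < 1:
        raise ValueError("initial model needs at least one resonance")
    bandwidth = 1.0 / fids.dwell
    if np.any(np.abs(init.frequencies_hz) > bandwidth / 2):
        raise ValueError(
            "initial frequencies must lie within the acquisition bandwidth "
            f"(+-{bandwidth / 2:.0f} Hz)"
        )
    t = fids.time_axis
    dreal = _real_stack(fids.data.T)  # (2 n_t, B)

    def unpack(x):
        return x[:k], x[k : 2 * k], x[2 * k]

    def resid(x):
        f, r, ph = unpack(x)
        breal = _real_stack(_basis(t, f, r, ph))
        amps = _solve_amplitudes(breal, dreal)
        return (dreal - breal @ amps).ravel()

    x0 = np.concatenate([init.frequencies_hz, init.r2star, [init.phase]])
    lb = np.concatenate([np.full(k, -bandwidth / 2), np.full(k, 1e-3), [-np.pi]])
    ub = np.concatenate([np.full(k, bandwidth / 2), np.full(k, 1e4), [np.pi]])
    sol = least_squares(
        resid, x0, bounds=(lb, ub), method="trf", max_nfev=max_nfev, x_scale="jac"
    )
    if not sol.success:
        raise RuntimeError(
            f"FID fit did not converge: {sol.message} (status {sol.status}, "
            f"nfev {sol.nfev}, final cost {sol.cost:.4g})"
        )
    f, r, ph = unpack(sol.x)
    breal = _real_stack(_basis(t, f, r, ph))
    amps = _solve_amplitudes(breal, dreal).T  # (B, K)
    resid_blocks = dreal - breal @ amps.T
    res_power = np.einsum("ib,ib->b", resid_blocks, resid_blocks)

    # near-degenerate frequency pairs: closer than half the wider linewidth
    degenerate_pairs = []
    lw = r / np.pi  # Lorentzian FWHM in Hz
    for i in range(k):
        for j in range(i + 1, k):
            if abs(f[i] - f[j]) < 0.5 * max(lw[i], lw[j]):
                degenerate_pairs.append((init.resonances[i], init.resonances[j]))
    if degenerate_pairs:
        warnings.warn(
            f"near-degenerate resonance frequencies: {degenerate_pairs}; "
            "amplitude estimates may trade off",
            RuntimeWarning,
            stacklevel=2,
        )

    amp_sd, f_sd, r_sd, ph_sd = _laplace_sds(t, f, r, ph, amps, resid_blocks)
    return SpectralModel(
        resonances=list(init.resonances),
        frequencies_hz=f,
        r2star=r,
        amplitudes=amps,
        phase=ph,
        amplitude_sd=amp_sd,
        frequency_sd=f_sd,
        r2star_sd=r_sd,
        phase_sd=ph_sd,
        residual_power=res_power,
        meta={
            "nfev": int(sol.nfev),
            "cost": float(sol.cost),
            "degenerate_pairs": degenerate_pairs,
            "hz_per_ppm": fids.f0_mhz,
            "ppm_ref": fids.ppm_ref,
            "block_times_min": fids.block_times.tolist(),
            "block_duration_min": fids.meta.get("block_duration_min"),
        },
    )


def _laplace_sds(t, f, r, ph, amps, resid_blocks):
    """SDs from the full-parameter covariance at the optimum.

    Parameters ordered: B*K amplitudes, K frequencies, K decay rates, phase.
    The Jacobian is analytic; sigma^2 is the residual variance.
    """
    n_b, k = amps.shape
    n_t = len(t)
    basis = _basis(t, f, r, ph)  # (n_t, K) complex
    dm_df = basis * (1j * 2.0 * np.pi * t[:, None])
    dm_dr = basis * (-t[:, None])
    n_obs = 2 * n_t * n_b
    n_par = n_b * k + 2 * k + 1
    J = np.zeros((n_obs, n_par))
    for b in range(n_b):
        rows = slice(2 * n_t * b, 2 * n_t * (b + 1))
        Jb = np.zeros((2 * n_t, n_par))
        Jb[:, b * k : (b + 1) * k] = _real_stack(basis)
        Jb[:, n_b * k : n_b * k + k] = _real_stack(dm_df * amps[b][None, :])
        Jb[:, n_b * k + k : n_b * k + 2 * k] = _real_stack(dm_dr * amps[b][None, :])
        model_b = basis @ amps[b]
        Jb[:, -1] = _real_stack((1j * model_b)[:, None])[:, 0]
        J[rows] = Jb
    rss = float(np.einsum("ib,ib->", resid_blocks, resid_blocks))
    dof = max(n_obs - n_par, 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.pinv(J.T @ J)
    d = np.sqrt(np.abs(np.diag(cov)))
    amp_sd = d[: n_b * k].reshape(n_b, k)
    f_sd = d[n_b * k : n_b * k + k]
    r_sd = d[n_b * k + k : n_b * k + 2 * k]
    ph_sd = float(d[-1])
    return amp_sd, f_sd, r_sd, ph_sd


def bootstrap_amplitude_sd(
    fids: FIDSeries,
    model: SpectralModel,
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Residual-bootstrap amplitude SDs — a non-Gaussian cross-check.

    Resamples the fitted model's complex residuals (with replacement,
    per block), refits, and returns the SD of the bootstrap amplitude
    estimates, shape (n_blocks, n_resonances).  Useful when the Laplace
    (covariance) SDs are suspect, e.g. near-degenerate resonances.
    """
    t = fids.time_axis
    basis = _basis(t, model.frequencies_hz, model.r2star, model.phase)
    fitted = model.amplitudes @ basis.T  # (B, n_t)
    resid = fids.data - fitted
    rng = np.random.default_rng(seed)
    init = SpectralModel(
        resonances=list(model.resonances),
        frequencies_hz=model.frequencies_hz,
        r2star=model.r2star,
        amplitudes=model.amplitudes,
        phase=model.phase,
    )
    draws = np.empty((n_boot,) + model.amplitudes.shape)
    for i in range(n_boot):
        idx = rng.integers(0, fids.n_points, size=fids.n_points)
        boot = FIDSeries(
            data=fitted + resid[:, idx],
            dwell=fids.dwell,
            f0_mhz=fids.f0_mhz,
            ppm_ref=fids.ppm_ref,
            block_times=fids.block_times,
            meta=dict(fids.meta),
        )
        draws[i] = fit_fid_series(boot, init).amplitudes
    return draws.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# corrections and absolute quantification
# ---------------------------------------------------------------------------


def correct_amplitudes(model: SpectralModel, cfg: QuantConfig) -> SpectralModel:
    """Divide out stoichiometry and relaxation attenuation per resonance.

    A_corr = A_fit / [stoich x (1 - exp(-TR/T1)) x exp(-TE/T2)], with the
    saturation factor assuming an ideal 90-degree excitation every TR.
    Corrected amplitudes are proportional to molecule concentration.
    """
    factors = np.array([cfg.correction_factor(name) for name in model.resonances])
    amp = model.amplitudes / factors[None, :]
    amp_sd = None if model.amplitude_sd is None else model.amplitude_sd / factors[None, :]
    return replace(
        model,
        amplitudes=amp,
        amplitude_sd=amp_sd,
        meta=dict(model.meta, corrected=True, correction_factors=factors.tolist()),
    )


def to_concentrations(
    model: SpectralModel,
    cfg: QuantConfig,
    pre_blocks: "tuple[int, ...] | list[int]" = (0, 1),
) -> MetaboliteTimeCourse:
    """Scale corrected amplitudes to mM via the HOD internal reference.

    The reference is the mean corrected HOD amplitude over the pre-infusion
    blocks, assigned the natural-abundance concentration; uncertainties are
    propagated to first order including the reference's own uncertainty.
    """
    pre = list(pre_blocks)
    if not pre:
        raise ValueError("pre_blocks must be nonempty")
    if not model.meta.get("corrected"):
        model = correct_amplitudes(model, cfg)
    j_hod = model.index("HOD")
    ref = float(model.amplitudes[pre, j_hod].mean())
    if ref <= 0:
        raise ValueError(f"HOD reference amplitude {ref:.4g} is not positive")
    if model.amplitude_sd is not None:
        ref_var = float(np.sum(model.amplitude_sd[pre, j_hod] ** 2)) / len(pre) ** 2
        amp_sd = model.amplitude_sd
    else:
        ref_var = 0.0
        amp_sd = np.zeros_like(model.amplitudes)

    scale = cfg.c_na / ref
    raw = model.amplitudes * scale
    var = (scale * amp_sd) ** 2 + (model.amplitudes * cfg.c_na / ref**2) ** 2 * ref_var
    times = np.asarray(model.meta.get("block_times_min", np.arange(model.n_blocks)), dtype=float)
    return MetaboliteTimeCourse(
        resonances=list(model.resonances),
        times_min=times,
        concentrations=np.maximum(raw, 0.0),
        raw=raw,
        sd=np.sqrt(var),
        meta={
            "reference_amplitude": ref,
            "reference_sd": float(np.sqrt(ref_var)),
            "c_na_mM": cfg.c_na,
            "pre_blocks": pre,
        },
    )


def glx_lac_timecourse(tc: MetaboliteTimeCourse) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block Glx:Lac ratio with propagated SD.

    Uses the raw (unfloored) estimates; blocks where Lac is consistent with
    zero (point estimate below twice its SD) are flagged undefined (NaN in
    the ratio, True in the flag array) rather than reported.
    """
    j_glx = tc.resonances.index("Glx")
    j_lac = tc.resonances.index("Lac")
    glx, lac = tc.raw[:, j_glx], tc.raw[:, j_lac]
    s_glx, s_lac = tc.sd[:, j_glx], tc.sd[:, j_lac]
    undefined = lac < 2.0 * s_lac
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, np.nan, glx / lac)
        rel_var = np.where(glx != 0, (s_glx / np.where(glx == 0, 1, glx)) ** 2, 0.0) + np.where(
            lac != 0, (s_lac / np.where(lac == 0, 1, lac)) ** 2, 0.0
        )
        ratio_sd = np.where(undefined, np.nan, np.abs(ratio) * np.sqrt(rel_var))
    return ratio, ratio_sd, undefined


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------


def standard_addition(series: TitrationSeries) -> tuple[float, float]:
    """Estimate the natural-abundance concentration by standard addition.

    Ordinary least squares of amplitude on added concentration; the
    x-intercept magnitude a/b estimates the endogenous concentration.  The
    SE follows from the delta method on (a, b).
    """
    deltas, amps = series.deltas, series.amplitudes
    if len(np.unique(deltas)) < 3:
        raise ValueError("standard addition needs at least 3 distinct added concentrations")
    if not np.any(deltas == 0):
        raise ValueError("titration series must include the un-spiked (delta = 0) sample")
    X = np.column_stack([np.ones_like(deltas), deltas])
    coef, *_ = np.linalg.lstsq(X, amps, rcond=None)
    a, b = coef
    if b <= 0:
        raise ValueError(f"fitted gain {b:.4g} is not positive; titration response is non-physical")
    n = len(deltas)
    resid = amps - X @ coef
    dof = max(n - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    c_hat = a / b
    grad = np.array([1.0 / b, -a / b**2])
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return float(c_hat), se


def ppm_to_concentration(ratio_ppm: float) -> float:
    """2H mole fraction (ppm of exchangeable hydrogens) -> HOD mM.

    Water carries 111.1 M of equivalent 1H sites, so a mole fraction of
    x ppm corresponds to x * 1e-6 * 111,100 mM of HOD.
    """
    if ratio_ppm < 0:
        raise ValueError("mole fraction must be non-negative")
    return ratio_ppm * 1e-6 * WATER_EQUIV_PROTON_M * 1e3


def glucose_dose_moles(mass_mg: float, molar_mass: float = GLC_66D2_MOLAR_MASS) -> float:
    """Moles of [6,6-2H2]glucose in a dose of ``mass_mg`` milligrams."""
    if mass_mg < 0:
        raise ValueError("dose must be non-negative")
    return mass_mg * 1e-3 / molar_mass
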