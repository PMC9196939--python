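"""Voxelwise parametric mapping: R1 (VFA), R2 (multi-echo), ADC, MTR.

Signal models:

* variable flip angle (spoiled gradient echo), fitted for (S_Boltzmann, R1):
      S(theta) = S0 (1 - E1) sin(theta) / (1 - E1 cos(theta)),  E1 = exp(-TR R1)
* multi-echo spin echo with an additive offset, fitted for (S(0), R2, C):
      S(TE) = S(0) exp(-TE R2) + C
* diffusion, log-linear weighted least squares over the six unique tensor
  elements with supplied b-matrices; ADC = trace(D)/3
* magnetization transfer ratio: MTR = 100 (OFF - ON) / OFF

The nonlinear fits run as a vectorised Levenberg-Marquardt over all masked
voxels simultaneously (analytic Jacobians, per-voxel damping), initialised
from the linearised forms (DESPOT1-style for VFA, offset-subtracted
log-linear for the echo train).  Flip angles are taken as nominal: no B1
correction is applied, so VFA R1 inherits any MT/B1 bias of the acquisition.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionSpec
from .containers import ImageStack, ParametricMap

#: background exclusion: voxels whose mean signal is below this multiple of
#: the estimated noise floor are never fitted.
NOISE_FLOOR_MULTIPLE = 5.0


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(stack: ImageStack, sigma: float = 0.75) -> ImageStack:
    """In-plane Gaussian smoothing (sigma in voxels), per volume.

    sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return stack
    sigmas = (sigma, sigma, 0.0) if stack.data.ndim == 3 else (sigma, sigma, 0.0, 0.0)
    out = ndimage.gaussian_filter(stack.data.astype(float), sigmas)
    meta = dict(stack.meta, preprocess_sigma=sigma)
    return ImageStack(data=out, voxel_size=stack.voxel_size, axis=stack.axis, meta=meta)


def estimate_noise_floor(stack: ImageStack) -> float:
    """Rough Rayleigh noise floor from the lowest-intensity decile.

    In a magnitude image the signal-free background follows a Rayleigh
    distribution with mean sd * sqrt(pi/2); the median of the lowest decile
    of mean intensities is a serviceable stand-in when no noise scan exists.
    If the lowest decile is comparable to the bulk intensity the field of
    view has no air background and the floor is reported as zero.
    """
    mean_img = stack.data.mean(axis=-1) if stack.data.ndim == 4 else stack.data
    flat = np.sort(mean_img.ravel())
    decile = float(np.median(flat[: max(len(flat) // 10, 1)]))
    overall = float(np.median(flat))
    if overall > 0 and decile > 0.2 * overall:
        return 0.0
    return decile


def _fit_mask(stack: ImageStack, threshold: float | None) -> tuple[np.ndarray, float]:
    mean_img = stack.data.mean(axis=-1) if stack.data.ndim == 4 else stack.data
    if threshold is None:
        threshold = NOISE_FLOOR_MULTIPLE * estimate_noise_floor(stack)
    floor = max(threshold, 1e-12 * max(float(mean_img.max()), 1.0))
    return mean_img > floor, floor


# ---------------------------------------------------------------------------
# batched Levenberg-Marquardt
# ---------------------------------------------------------------------------


def _batched_lm(p0, residual, jacobian, max_iter=80, tol=1e-14):
    """Minimise sum-of-squares per voxel for a small-parameter model.

    p0 : (nvox, npar) initial parameters.
    residual(p) -> (nvox, nobs); jacobian(p) -> (nvox, nobs, npar).
    Returns (p, converged, cov_scale) where cov_scale is (J^T J)^-1.
    """
    p = np.array(p0, dtype=float)
    nvox, npar = p.shape
    lam = np.full(nvox, 1e-3)
    eye = np.eye(npar)
    # overflow/NaN in a rejected trial step is expected and harmless
    with np.errstate(over="ignore", invalid="ignore"):
        r = residual(p)
        cost = np.einsum("vi,vi->v", r, r)
        for _ in range(max_iter):
            J = jacobian(p)
            jtj = np.einsum("vik,vil->vkl", J, J)
            jtr = np.einsum("vik,vi->vk", J, r)
            # LM with diagonal (Marquardt) scaling; tiny ridge guards singularity
            diag = np.einsum("vkk->vk", jtj)
            A = jtj + lam[:, None, None] * (diag[:, :, None] * eye) + 1e-30 * eye
            try:
                step = np.linalg.solve(A, -jtr[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = -np.einsum("vkl,vl->vk", np.linalg.pinv(A), jtr)
            p_new = p + step
            r_new = residual(p_new)
            cost_new = np.einsum("vi,vi->v", r_new, r_new)
            better = cost_new <= cost
            p = np.where(better[:, None], p_new, p)
            r = np.where(better[:, None], r_new, r)
            cost = np.where(better, cost_new, cost)
            lam = np.clip(np.where(better, lam / 3.0, lam * 10.0), 1e-12, 1e14)
            small = np.abs(step).max(axis=1) <= tol * (1.0 + np.abs(p).max(axis=1))
            if np.all(better & small):
                break
        J = jacobian(p)
        jtj = np.einsum("vik,vil->vkl", J, J)
        cov_scale = np.linalg.pinv(jtj)
        converged = np.isfinite(cost)
        out = residual(p)
    return p, converged, cov_scale, out


def _uncertainty(cov_scale: np.ndarray, resid: np.ndarray, npar: int) -> np.ndarray:
    nobs = resid.shape[1]
    dof = max(nobs - npar, 1)
    sigma2 = np.einsum("vi,vi->v", resid, resid) / dof
    return np.sqrt(np.abs(sigma2[:, None] * np.einsum("vkk->vk", cov_scale)))


def _to_map(shape, mask, values, sd, param, units, meta, report):
    out_v = np.full(shape, np.nan)
    out_s = np.full(shape, np.nan)
    out_v[mask] = values
    out_s[mask] = sd
    return ParametricMap(
        values=out_v, uncertainty=out_s, mask=mask, param=param, units=units, meta=meta,
        report=report,
    )


# ---------------------------------------------------------------------------
# R1 from variable flip angles
# ---------------------------------------------------------------------------


def fit_r1_vfa(
    stack: ImageStack, acq: AcquisitionSpec, mask_threshold: float | None = None
) -> ParametricMap:
    """Voxelwise nonlinear VFA fit for (S_Boltzmann, R1).

    Initialisation comes from the DESPOT1 linearisation S/sin vs S/tan,
    refined by full nonlinear least squares.  Voxels that end with
    non-physical R1 are flagged out of the mask (and counted), not raised.
    """
    if acq.sequence != "vfa":
        raise ValueError("acquisition is not a variable-flip-angle spec")
    angles = np.asarray(acq.flip_angles_deg, dtype=float)
    if len(np.unique(angles)) < 3:
        raise ValueError("VFA fit needs at least 3 distinct flip angles")
    tr = acq.tr
    mask, _ = _fit_mask(stack, mask_threshold)
    y = stack.data[mask]  # (nvox, nang)
    th = np.deg2rad(angles)
    sin_t, cos_t, tan_t = np.sin(th), np.cos(th), np.tan(th)

    # DESPOT1 init: S/sin = E1 * S/tan + S0 (1 - E1)
    ylin = y / sin_t
    xlin = y / tan_t
    xm = xlin.mean(axis=1, keepdims=True)
    ym = ylin.mean(axis=1, keepdims=True)
    sxx = np.einsum("vi,vi->v", xlin - xm, xlin - xm)
    sxy = np.einsum("vi,vi->v", xlin - xm, ylin - ym)
    e1 = np.clip(sxy / np.maximum(sxx, 1e-30), 1e-6, 1.0 - 1e-6)
    r1_0 = -np.log(e1) / tr
    s0_0 = np.maximum((ym[:, 0] - e1 * xm[:, 0]) / (1.0 - e1), 1e-12)

    def model(p):
        s0, r1 = p[:, 0:1], p[:, 1:2]
        e = np.exp(-tr * r1)
        return s0 * (1.0 - e) * sin_t / (1.0 - e * cos_t)

    def residual(p):
        return model(p) - y

    def jacobian(p):
        s0, r1 = p[:, 0:1], p[:, 1:2]
        e = np.exp(-tr * r1)
        denom = 1.0 - e * cos_t
        m = s0 * (1.0 - e) * sin_t / denom
        dm_de = s0 * sin_t * (cos_t - 1.0) / denom**2
        J = np.empty(p.shape[:1] + m.shape[1:] + (2,))
        J[..., 0] = m / np.maximum(s0, 1e-300)
        J[..., 1] = dm_de * (-tr * e)
        return J

    p0 = np.column_stack([s0_0, np.clip(r1_0, 1e-4, 1e3)])
    p, _, cov_scale, resid = _batched_lm(p0, residual, jacobian)
    sd = _uncertainty(cov_scale, resid, 2)

    r1 = p[:, 1]
    bad = ~np.isfinite(r1) | (r1 <= 0)
    full_mask = mask.copy()
    idx = np.flatnonzero(mask)
    full_mask.flat[idx[bad]] = False
    report = {"n_fitted": int((~bad).sum()), "n_flagged_nonphysical": int(bad.sum())}
    return _to_map(
        stack.shape3d,
        full_mask,
        r1[~bad],
        sd[~bad, 1],
        "R1",
        "s^-1",
        {"model": "vfa_r1", "tr_s": tr, "flip_angles_deg": angles.tolist(),
         "amplitude": "S_Boltzmann"},
        report,
    )


# ---------------------------------------------------------------------------
# R2 from the echo train
# ---------------------------------------------------------------------------


def fit_r2_mems(
    stack: ImageStack, acq: AcquisitionSpec, mask_threshold: float | None = None
) -> ParametricMap:
    """Voxelwise 3-parameter fit S(TE) = S(0) exp(-TE R2) + Constant.

    The additive constant absorbs noise-floor/stimulated-echo offsets; a
    2-parameter fit on offset-contaminated data biases R2 low, which is why
    the constant is kept free.  Initialised by a log-linear fit of the
    offset-subtracted echo train.
    """
    if acq.sequence != "mems":
        raise ValueError("acquisition is not a multi-echo spin-echo spec")
    te = np.asarray(acq.te_list, dtype=float)
    if len(te) < 4:
        raise ValueError("R2 fit needs at least 4 echoes for 3 free parameters")
    mask, _ = _fit_mask(stack, mask_threshold)
    y = stack.data[mask]

    c0 = 0.9 * y.min(axis=1, keepdims=True)
    resid0 = np.maximum(y - c0, 1e-12 * np.maximum(y.max(axis=1, keepdims=True), 1e-30))
    logs = np.log(resid0)
    tm = te.mean()
    lm = logs.mean(axis=1)
    stt = np.sum((te - tm) ** 2)
    slope = np.einsum("i,vi->v", te - tm, logs - lm[:, None]) / stt
    r2_0 = np.clip(-slope, 1e-4, 1e4)
    a0 = np.exp(lm + r2_0 * tm)

    def residual(p):
        a, r2, c = p[:, 0:1], p[:, 1:2], p[:, 2:3]
        return a * np.exp(-te * r2) + c - y

    def jacobian(p):
        a, r2 = p[:, 0:1], p[:, 1:2]
        e = np.exp(-te * r2)
        J = np.empty((p.shape[0], len(te), 3))
        J[..., 0] = np.broadcast_to(e, (p.shape[0], len(te)))
        J[..., 1] = -a * te * e
        J[..., 2] = 1.0
        return J

    p0 = np.column_stack([a0, r2_0, c0[:, 0]])
    p, _, cov_scale, resid = _batched_lm(p0, residual, jacobian)
    sd = _uncertainty(cov_scale, resid, 3)

    amp, r2 = p[:, 0], p[:, 1]
    scale = np.maximum(np.abs(amp) + np.abs(p[:, 2]), 1e-30)
    degenerate = (r2 < 1e-3) | (np.abs(amp) < 1e-6 * scale)
    bad = ~np.isfinite(r2) | (r2 < 0)
    full_mask = mask.copy()
    idx = np.flatnonzero(mask)
    full_mask.flat[idx[bad]] = False
    report = {
        "n_fitted": int((~bad).sum()),
        "n_flagged_nonphysical": int(bad.sum()),
        "n_flagged_degenerate": int((degenerate & ~bad).sum()),
    }
    degen_map = np.zeros(stack.shape3d, dtype=bool)
    degen_map.flat[idx[degenerate & ~bad]] = True
    return _to_map(
        stack.shape3d,
        full_mask,
        r2[~bad],
        sd[~bad, 1],
        "R2",
        "s^-1",
        {"model": "mems_r2", "te_s": te.tolist(), "degenerate_mask": degen_map},
        report,
    )


# ---------------------------------------------------------------------------
# ADC from the diffusion tensor trace
# ---------------------------------------------------------------------------


def fit_adc(
    stack: ImageStack, acq: AcquisitionSpec, mask_threshold: float | None = None
) -> ParametricMap:
    """Log-linear weighted tensor fit; ADC = trace(D)/3 in um^2/ms.

    ln S = ln S(0) - sum_ij b_ij D_ij over the six unique tensor elements,
    solved per voxel by weighted least squares with weights S^2 (the
    first-order noise propagation of the log transform).  b-matrices are
    inputs in s/mm^2; the 1e-3 factor makes fitted D come out in um^2/ms.
    Voxels with a negative-definite tensor are flagged.
    """
    if acq.sequence != "dwi":
        raise ValueError("acquisition is not a diffusion spec")
    bmats = np.asarray(acq.b_matrices, dtype=float)
    design = np.empty((len(bmats), 7))
    design[:, 0] = 1.0
    # D ordering: xx, yy, zz, xy, xz, yz; off-diagonals count twice
    design[:, 1] = -1e-3 * bmats[:, 0, 0]
    design[:, 2] = -1e-3 * bmats[:, 1, 1]
    design[:, 3] = -1e-3 * bmats[:, 2, 2]
    design[:, 4] = -2e-3 * bmats[:, 0, 1]
    design[:, 5] = -2e-3 * bmats[:, 0, 2]
    design[:, 6] = -2e-3 * bmats[:, 1, 2]
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        raise ValueError(
            f"diffusion encoding is rank-deficient: design rank {rank} < 7; "
            "need >= 6 independent b-matrices plus one b~0 volume"
        )
    mask, _ = _fit_mask(stack, mask_threshold)
    y = stack.data[mask]
    pos = y > 0
    safe = np.where(pos, y, 1.0)
    logs = np.log(safe)
    w = np.where(pos, y**2, 0.0)  # WLS weights; non-positive signals dropped

    A = np.einsum("vi,ip,iq->vpq", w, design, design)
    b = np.einsum("vi,ip,vi->vp", w, design, logs)
    try:
        beta = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.einsum("vpq,vq->vp", np.linalg.pinv(A), b)

    adc = beta[:, 1:4].sum(axis=1) / 3.0
    # uncertainty: sigma^2 (X^T W X)^-1 on the log scale
    fitted = np.einsum("ip,vp->vi", design, beta)
    rw = (logs - fitted) * np.sqrt(w)
    dof = max(len(bmats) - 7, 1)
    sigma2 = np.einsum("vi,vi->v", rw, rw) / dof
    covs = np.linalg.pinv(A)
    trace_var = covs[:, 1:4, 1:4].sum(axis=(1, 2)) / 9.0
    sd = np.sqrt(np.abs(sigma2 * trace_var))

    tensors = np.zeros((len(beta), 3, 3))
    tensors[:, 0, 0] = beta[:, 1]
    tensors[:, 1, 1] = beta[:, 2]
    tensors[:, 2, 2] = beta[:, 3]
    tensors[:, 0, 1] = tensors[:, 1, 0] = beta[:, 4]
    tensors[:, 0, 2] = tensors[:, 2, 0] = beta[:, 5]
    tensors[:, 1, 2] = tensors[:, 2, 1] = beta[:, 6]
    eigmin = np.linalg.eigvalsh(tensors)[:, 0]
    negdef = eigmin < -1e-12

    bad = ~np.isfinite(adc)
    full_mask = mask.copy()
    idx = np.flatnonzero(mask)
    full_mask.flat[idx[bad]] = False
    negdef_map = np.zeros(stack.shape3d, dtype=bool)
    negdef_map.flat[idx[negdef & ~bad]] = True
    report = {
        "n_fitted": int((~bad).sum()),
        "n_flagged_nonfinite": int(bad.sum()),
        "n_flagged_negative_definite": int((negdef & ~bad).sum()),
    }
    return _to_map(
        stack.shape3d,
        full_mask,
        adc[~bad],
        sd[~bad],
        "ADC",
        "um^2/ms",
        {"model": "dwi_adc", "negative_definite_mask": negdef_map},
        report,
    )


# ---------------------------------------------------------------------------
# MTR
# ---------------------------------------------------------------------------


def compute_mtr(
    on: ImageStack, off: ImageStack, off_threshold: float | None = None
) -> ParametricMap:
    """MTR = 100 (OFF - ON) / OFF, percent.

    Voxels with OFF at or below the background threshold are masked out;
    values escaping [0, 100] (possible under noise) are flagged and removed
    from the mask rather than clipped silently.
    """
    on_d = on.data if on.data.ndim == 3 else on.data[..., 0]
    off_d = off.data if off.data.ndim == 3 else off.data[..., 0]
    if on_d.shape != off_d.shape:
        raise ValueError(f"ON/OFF shape mismatch: {on_d.shape} vs {off_d.shape}")
    if off_threshold is None:
        off_stack = ImageStack(data=off_d, voxel_size=off.voxel_size)
        off_threshold = NOISE_FLOOR_MULTIPLE * estimate_noise_floor(off_stack)
    floor = max(off_threshold, 1e-12 * max(float(off_d.max()), 1.0))
    valid = off_d > floor
    mtr = np.full(off_d.shape, np.nan)
    np.divide(100.0 * (off_d - on_d), off_d, out=mtr, where=valid)
    in_range = valid & (mtr >= 0.0) & (mtr <= 100.0)
    report = {
        "n_fitted": int(in_range.sum()),
        "n_below_threshold": int((~valid).sum()),
        "n_flagged_out_of_range": int((valid & ~in_range).sum()),
    }
    return ParametricMap(
        values=mtr,
        uncertainty=np.zeros_like(mtr),
        mask=in_range,
        param="MTR",
        units="percent",
        meta={"model": "mtr", "off_threshold": floor},
        report=report,
    )


def split_mt_pair(stack: ImageStack) -> tuple[ImageStack, ImageStack]:
    """Split a simulated MT stack (volumes ordered per mt_states) into
    (on, off) single-volume stacks."""
    states = stack.meta.get("mt_states", ["off", "on"])
    vols = {s: stack.data[..., i] for i, s in enumerate(states)}
    mk = lambda d: ImageStack(data=d, voxel_size=stack.voxel_size, meta=dict(stack.meta))
    return mk(vols["on"]), mk(vols["off"])
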