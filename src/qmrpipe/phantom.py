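"""Digital mouse-brain phantom: forward simulation of every pipeline input.

A 2-D multislice label map (background / cortex / muscle / lesion labels)
is populated with tissue presets, and each acquisition is simulated with
its exact forward signal model, so a noiseless simulate-then-fit round trip
is an identity check on the fitting code.  Measurement noise is Rician on
1H magnitude images and complex circular Gaussian on raw 2H FIDs, matching
how each modality is actually recorded.

Lesion layouts mirror the study cohorts: a pure-tumor lesion, a pure
radiation-necrosis lesion, a mixed lesion with disjoint tumor and RN
compartments, and a lesion-free control, all in the left hemisphere with
contralateral cortex and a temporalis/masseter muscle band.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionSpec
from .containers import FIDSeries, ImageStack, TitrationSeries
from .presets import (
    C_NA_MM,
    DMRS_F0_MHZ,
    CHEMICAL_SHIFTS_PPM,
    DmrsKinetics,
    TissuePreset,
    study_defaults,
)

LABELS = {"background": 0, "cortex": 1, "muscle": 2, "tumor": 3, "rn": 4}
LAYOUTS = ("tumor", "rn", "mixed", "control")

#: which preset each label uses, per layout (mixed lesions carry the
#: admixed-lesion parameter values)
_LAYOUT_PRESETS = {
    "tumor": {"tumor": "tumor"},
    "rn": {"rn": "rn"},
    "mixed": {"tumor": "tumor_in_mixed", "rn": "rn_in_mixed"},
    "control": {},
}


@dataclass
class PhantomSpec:
    """A label map plus per-label tissue presets and a noise model."""

    label_map: np.ndarray  # integer (nx, ny, nz)
    presets: dict[int, TissuePreset]
    voxel_size: tuple[float, float, float]  # mm
    noise: str = "none"  # none | gaussian | rician
    noise_sd: float = 0.0  # SD relative to lesion/cortex s0
    seed: int = 0
    layout: str = "control"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 3:
            raise ValueError("label_map must be 3-D")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        present = set(np.unique(self.label_map)) - {0}
        missing = present - set(self.presets)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no tissue preset")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    def mask(self, label_name: str) -> np.ndarray:
        return self.label_map == LABELS[label_name]

    def param_volume(self, getter) -> np.ndarray:
        """Assemble a voxel volume by broadcasting a per-preset scalar."""
        out = np.zeros(self.label_map.shape, dtype=float)
        for lab, preset in self.presets.items():
            out[self.label_map == lab] = getter(preset)
        return out


def build_label_map(
    matrix: tuple[int, int] = (64, 64),
    n_slices: int = 21,
    fov_mm: tuple[float, float] = (16.0, 16.0),
    slice_thickness_mm: float = 0.5,
    lesion_layout: str = "tumor",
    presets: dict[str, TissuePreset] | None = None,
    noise: str = "none",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Build the digital phantom for one cohort layout.

    The brain is an in-plane ellipse spanning the central slices; the left
    hemisphere hosts the lesion disk(s), the contralateral side is cortex,
    and a muscle band sits ventrally.  Geometry is deterministic; the seed
    only drives the noise realisation of subsequent simulations.
    """
    if lesion_layout not in LAYOUTS:
        raise ValueError(f"unknown lesion layout {lesion_layout!r}; expected one of {LAYOUTS}")
    if matrix[0] <= 0 or matrix[1] <= 0 or n_slices <= 0:
        raise ValueError("matrix size and slice count must be positive")
    if fov_mm[0] <= 0 or fov_mm[1] <= 0 or slice_thickness_mm <= 0:
        raise ValueError("FOV and slice thickness must be positive")

    nx, ny = matrix
    lab = np.zeros((nx, ny, n_slices), dtype=np.int16)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    # brain ellipse (fractions of matrix so any size works)
    cx, cy = 0.50 * nx, 0.42 * ny
    rx, ry = 0.36 * nx, 0.30 * ny
    brain = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    # muscle: two ventro-lateral bands below the brain
    muscle = (y >= 0.78 * ny) & (y <= 0.92 * ny) & (np.abs(x - cx) <= 0.38 * nx)

    # lesion disks in the left hemisphere (low-x half)
    def disk(fx: float, fy: float, fr: float) -> np.ndarray:
        return (x - fx * nx) ** 2 + (y - fy * ny) ** 2 <= (fr * nx) ** 2

    lesions: dict[str, np.ndarray] = {}
    if lesion_layout == "tumor":
        lesions["tumor"] = disk(0.31, 0.40, 0.12) & brain
    elif lesion_layout == "rn":
        lesions["rn"] = disk(0.31, 0.40, 0.14) & brain
    elif lesion_layout == "mixed":
        lesions["tumor"] = disk(0.27, 0.33, 0.085) & brain
        lesions["rn"] = disk(0.33, 0.52, 0.085) & brain
        overlap = lesions["tumor"] & lesions["rn"]
        lesions["rn"] &= ~overlap  # keep compartments disjoint

    central = slice(max(n_slices // 8, 1), n_slices - max(n_slices // 8, 1))
    for z in range(n_slices)[central]:
        sl = np.zeros((nx, ny), dtype=np.int16)
        sl[brain] = LABELS["cortex"]
        for name, m in lesions.items():
            sl[m] = LABELS[name]
        sl[muscle] = LABELS["muscle"]
        lab[:, :, z] = sl

    profile = presets or study_defaults()
    preset_map = {LABELS["cortex"]: profile["cortex"], LABELS["muscle"]: profile["muscle"]}
    for name, preset_name in _LAYOUT_PRESETS[lesion_layout].items():
        preset_map[LABELS[name]] = profile[preset_name]

    voxel = (fov_mm[0] / nx, fov_mm[1] / ny, slice_thickness_mm)
    return PhantomSpec(
        label_map=lab,
        presets=preset_map,
        voxel_size=voxel,
        noise=noise,
        noise_sd=noise_sd,
        seed=seed,
        layout=lesion_layout,
        meta={"matrix": matrix, "n_slices": n_slices, "fov_mm": fov_mm},
    )


def roi_masks(phantom: PhantomSpec, erosion: int = 3) -> dict[str, np.ndarray]:
    """Conservative per-tissue ROI masks (in-plane erosion).

    Mirrors conservatively drawn ROIs that avoid lesion boundaries and
    partial-volume voxels.  The structuring element is a full in-plane
    3x3 square, so ``erosion`` steps guarantee a Chebyshev margin of the
    same width — enough to keep the truncated Gaussian support (radius 3
    voxels at the default sigma 0.75) of every ROI voxel inside its tissue.
    """
    struct = np.ones((3, 3, 1), dtype=bool)
    out: dict[str, np.ndarray] = {}
    for name, lab in LABELS.items():
        if name == "background":
            continue
        m = phantom.label_map == lab
        if not m.any():
            continue
        er = m
        for _ in range(erosion):
            er = ndimage.binary_erosion(er, structure=struct)
        if er.any():
            out[name] = er
    return out


# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------


def add_rician_noise(signal: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the noiseless signal perturbed by complex Gaussian noise.

    The mean magnitude converges to the true signal as SNR grows and to
    sd * sqrt(pi/2) where the true signal is zero.
    """
    n_re = rng.normal(0.0, sd, signal.shape)
    n_im = rng.normal(0.0, sd, signal.shape)
    return np.hypot(signal + n_re, n_im)


def _apply_noise(data: np.ndarray, phantom: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if phantom.noise == "none" or phantom.noise_sd == 0.0:
        return data
    ref_s0 = max(p.s0 for p in phantom.presets.values()) if phantom.presets else 1.0
    sd = phantom.noise_sd * ref_s0
    if phantom.noise == "gaussian":
        return data + rng.normal(0.0, sd, data.shape)
    return add_rician_noise(data, sd, rng)


# ---------------------------------------------------------------------------
# 1H forward models
# ---------------------------------------------------------------------------


def vfa_signal(s0: np.ndarray, r1: np.ndarray, tr: float, flip_deg: float) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal at one flip angle."""
    e1 = np.exp(-tr * r1)
    th = np.deg2rad(flip_deg)
    return s0 * (1.0 - e1) * np.sin(th) / (1.0 - e1 * np.cos(th))


def simulate_stack(
    phantom: PhantomSpec, acq: AcquisitionSpec, rng: np.random.Generator | None = None
) -> ImageStack:
    """Simulate one acquisition over the phantom.

    Noiseless output equals the forward model exactly; when the phantom
    requests noise it is applied per volume with the phantom's seed (or a
    caller-provided generator).
    """
    if rng is None:
        rng = np.random.default_rng(phantom.seed)
    lab3 = phantom.label_map
    s0 = phantom.param_volume(lambda p: p.s0)
    vols: list[np.ndarray] = []
    meta: dict[str, Any] = {"sequence": acq.sequence, "layout": phantom.layout}

    if acq.sequence == "vfa":
        r1 = phantom.param_volume(lambda p: p.r1)
        for th in acq.flip_angles_deg:
            vols.append(vfa_signal(s0, r1, acq.tr, th))
        axis = "flip_angle"
        meta["flip_angles_deg"] = list(map(float, acq.flip_angles_deg))
        meta["tr_s"] = acq.tr
    elif acq.sequence == "mems":
        r2 = phantom.param_volume(lambda p: p.r2)
        for te in acq.te_list:
            vols.append(s0 * np.exp(-te * r2))
        axis = "echo"
        meta["te_s"] = list(map(float, acq.te_list))
    elif acq.sequence == "dwi":
        # exponent: b (s/mm^2) x D (um^2/ms) x 1e-3 is dimensionless
        tensors = np.zeros(lab3.shape + (3, 3))
        for lab, preset in phantom.presets.items():
            tensors[lab3 == lab] = preset.adc_tensor
        for b in acq.b_matrices:
            expo = 1e-3 * np.einsum("...ij,ij->...", tensors, b)
            vols.append(s0 * np.exp(-expo))
        axis = "diffusion"
        meta["b_matrices"] = [b.tolist() for b in acq.b_matrices]
    elif acq.sequence == "mt":
        mtr = phantom.param_volume(lambda p: p.mtr)
        off = s0.copy()
        for state in acq.mt_states:
            vols.append(off if state == "off" else off * (1.0 - mtr / 100.0))
        axis = "mt_state"
        meta["mt_states"] = list(acq.mt_states)
        meta["mt_offset_hz"] = acq.mt_offset_hz
    elif acq.sequence == "dce":
        # every non-background tissue needs an enhancement curve (possibly flat)
        times = np.arange(acq.n_frames) * acq.frame_dt
        fe = np.zeros(lab3.shape + (acq.n_frames,))
        for lab, preset in phantom.presets.items():
            if preset.dce_curve is None:
                if (lab3 == lab).any():
                    raise ValueError(
                        f"preset {preset.name!r} lacks 'dce_curve' required by the dce sequence"
                    )
                continue
            fe[lab3 == lab] = preset.dce_curve.evaluate(times)
        data = s0[..., None] * (1.0 + fe)
        data = _apply_noise(data, phantom, rng)
        meta.update(n_frames=acq.n_frames, frame_dt_s=acq.frame_dt)
        return ImageStack(data=data, voxel_size=phantom.voxel_size, axis="frame", meta=meta)
    else:
        raise ValueError(f"simulate_stack does not handle sequence {acq.sequence!r}")

    data = np.stack(vols, axis=-1)
    data = _apply_noise(data, phantom, rng)
    return ImageStack(data=data, voxel_size=phantom.voxel_size, axis=axis, meta=meta)


def ground_truth_table(phantom: PhantomSpec) -> "list[dict[str, Any]]":
    """Per-label ground-truth parameter rows (for the CSV sidecar)."""
    rows = []
    for lab, preset in sorted(phantom.presets.items()):
        rows.append(
            {
                "label": lab,
                "name": preset.name,
                "r1_s-1": preset.r1,
                "r2_s-1": preset.r2,
                "adc_um2_ms": preset.adc,
                "mtr_percent": preset.mtr,
                "s0": preset.s0,
                "dce_amplitude": preset.dce_curve.amplitude if preset.dce_curve else np.nan,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# 2H forward models
# ---------------------------------------------------------------------------


def metabolite_amplitudes(
    kinetics: DmrsKinetics,
    acq: AcquisitionSpec,
    n_blocks: int,
    gain: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Noiseless per-block amplitudes (blocks x resonances) and block times.

    Amplitude = gain x concentration at block midpoint x stoichiometry x
    steady-state saturation factor x T2 echo attenuation — exactly the
    forward counterpart of the quantification's correction step.
    """
    from .presets import QuantConfig

    cfg = QuantConfig(
        relaxation=dict(kinetics.relaxation), tr=acq.tr, te=acq.te, c_na=kinetics.c_na
    )
    names = kinetics.resonances
    starts = np.arange(n_blocks) * acq.block_duration_min
    mids = starts + acq.block_duration_min / 2.0
    amps = np.zeros((n_blocks, len(names)))
    for j, name in enumerate(names):
        conc = np.asarray(kinetics.curves[name](mids), dtype=float)
        if np.any(conc < 0):
            raise ValueError(f"{name}: concentration curve goes negative")
        amps[:, j] = gain * conc * cfg.correction_factor(name)
    return amps, starts, names


def simulate_fid_series(
    kinetics: DmrsKinetics,
    acq: AcquisitionSpec,
    n_blocks: int = 11,
    seed: int = 0,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    phase: float = 0.0,
) -> FIDSeries:
    """Simulate the block-wise 2H FID series for one subject.

    Each block's FID is a sum of exponentially decaying sinusoids with the
    cohort's per-resonance frequency and R2*, amplitudes following the
    metabolite kinetics at the block midpoints, plus complex circular
    Gaussian noise.  Blocks before the infusion onset contain only the
    natural-abundance HOD resonance.
    """
    if n_blocks < 3:
        raise ValueError("need at least 3 blocks (two pre-infusion, one during infusion)")
    amps, starts, names = metabolite_amplitudes(kinetics, acq, n_blocks, gain)
    t = np.arange(acq.n_points) * acq.dwell
    freqs = np.array(
        [(kinetics.shifts_ppm[n] - CHEMICAL_SHIFTS_PPM["HOD"]) * DMRS_F0_MHZ for n in names]
    )
    r2s = np.array([kinetics.r2star[n] for n in names])
    basis = np.exp((1j * 2.0 * np.pi * freqs[None, :] - r2s[None, :]) * t[:, None])
    data = np.exp(1j * phase) * (amps @ basis.T)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return FIDSeries(
        data=data,
        dwell=acq.dwell,
        f0_mhz=DMRS_F0_MHZ,
        ppm_ref=CHEMICAL_SHIFTS_PPM["HOD"],
        block_times=starts,
        meta={
            "cohort": kinetics.cohort,
            "resonances": names,
            "true_frequencies_hz": freqs.tolist(),
            "true_r2star_s-1": r2s.tolist(),
            "true_amplitudes": amps.tolist(),
            "gain": gain,
            "noise_sd": noise_sd,
            "phase_rad": phase,
            "block_duration_min": acq.block_duration_min,
            "onset_min": kinetics.curves["Glc"].onset,
        },
    )


# ---------------------------------------------------------------------------
# standard-addition titration
# ---------------------------------------------------------------------------

DEFAULT_TITRATION_DELTAS = (0.0, 36.0, 72.0, 108.0, 144.0, 180.0)


def simulate_titration(
    delta_hod_mM: "tuple[float, ...] | np.ndarray" = DEFAULT_TITRATION_DELTAS,
    c_na: float = C_NA_MM,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Signal amplitudes of a standard-addition HOD titration series.

    amplitude_i = gain x (c_na + delta_i) + noise.  The default deltas are
    the five enrichment steps of 36 mM plus the un-spiked tap-water sample.
    """
    deltas = np.asarray(delta_hod_mM, dtype=float)
    if np.any(deltas < 0):
        raise ValueError("added concentrations must be non-negative")
    if c_na <= 0:
        raise ValueError("natural-abundance concentration must be positive")
    amps = gain * (c_na + deltas)
    if noise_sd > 0:
        amps = amps + np.random.default_rng(seed).normal(0.0, noise_sd, amps.shape)
    return TitrationSeries(
        deltas=deltas, amplitudes=amps, meta={"gain": gain, "c_na": c_na, "noise_sd": noise_sd}
    )
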