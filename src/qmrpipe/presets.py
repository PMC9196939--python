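"""Ground-truth tissue presets and quantification constants.

The digital phantom is parameterised by per-tissue quantitative truths
(R1, R2, diffusion tensor, MTR, DCE enhancement curve, equilibrium signal)
for the tissue classes of a mouse brain-lesion study: glioblastoma ("tumor"),
radiation necrosis ("rn"), their counterparts when the two pathologies are
admixed, contralateral cortex, and temporalis/masseter muscle.  Lesion
presets carry the study's reported group-mean parameter values so that a
noiseless simulate-then-fit round trip is a meaningful recovery test;
cortex and muscle presets are literature-informed defaults.

The deuterium side holds metabolite kinetics (glucose uptake, lactate vs
glutamate+glutamine production) per cohort, labeling stoichiometries,
published relaxation times, and the natural-abundance semiheavy-water (HOD)
internal reference concentration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# physical constants of the quantification
# ---------------------------------------------------------------------------

#: natural-abundance HOD concentration in regional tap (and hence tissue)
#: water, mM — the internal concentration reference.
C_NA_MM = 16.35

#: water is 111.1 M in equivalent 1H; converts a 2H mole-fraction (ppm)
#: to an HOD concentration in mM.
WATER_EQUIV_PROTON_M = 111.1

#: effective 2H labels surviving per molecule at detection: HOD carries one
#: deuteron; [6,6-2H2]glucose two; lactate 1.7 (2 labels, 15% loss);
#: Glx 1.2 (2 labels, 40% loss).
STOICHIOMETRY = {"HOD": 1.0, "Glc": 2.0, "Lac": 1.7, "Glx": 1.2}

#: molar mass of [6,6-2H2]glucose, g/mol (C6H10D2O6)
GLC_66D2_MOLAR_MASS = 182.17

#: 2H observe frequency, MHz (11.74 T)
DMRS_F0_MHZ = 76.65

#: chemical shifts, ppm (receiver reference on the water/HOD resonance)
CHEMICAL_SHIFTS_PPM = {"HOD": 4.8, "Glc": 3.8, "Glx": 2.4, "Lac": 1.3}

#: published 2H relaxation times (T1, T2) in seconds; literature defaults,
#: overridable through QuantConfig.
RELAXATION_S = {
    "HOD": (0.320, 0.030),
    "Glc": (0.064, 0.032),
    "Lac": (0.297, 0.061),
    "Glx": (0.146, 0.040),
}


# ---------------------------------------------------------------------------
# 1H imaging presets
# ---------------------------------------------------------------------------


@dataclass
class DceCurve:
    """Parametric contrast-enhancement curve (fractional enhancement units).

    Enhancement is zero through the baseline period, then rises
    mono-exponentially from the onset frame with optional washout:

        FE(t) = amplitude * (1 - exp(-k_up * dt)) * exp(-k_wash * dt)

    with ``dt`` the time since onset in seconds.
    """

    amplitude: float  # peak-scale fractional enhancement (dimensionless)
    onset_frame: int = 30  # 0-based first post-injection frame
    k_up: float = 0.02  # 1/s
    k_wash: float = 0.0  # 1/s

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("enhancement amplitude must be non-negative")
        if self.k_up <= 0 or self.k_wash < 0:
            raise ValueError("rate constants must be positive (k_up) / non-negative (k_wash)")

    def shape(self, frame_times_s: np.ndarray) -> np.ndarray:
        """Unit-amplitude curve evaluated at frame times (s from series start)."""
        t0 = frame_times_s[self.onset_frame] if self.onset_frame < len(frame_times_s) else np.inf
        dt = np.maximum(frame_times_s - t0, 0.0)
        out = (1.0 - np.exp(-self.k_up * dt)) * np.exp(-self.k_wash * dt)
        out[frame_times_s < t0] = 0.0
        return out

    def evaluate(self, frame_times_s: np.ndarray) -> np.ndarray:
        return self.amplitude * self.shape(frame_times_s)


@dataclass
class TissuePreset:
    """Quantitative ground truth for one tissue class."""

    name: str
    r1: float  # s^-1
    r2: float  # s^-1
    adc_tensor: np.ndarray  # symmetric 3x3, um^2/ms
    mtr: float  # percent
    s0: float = 100.0  # equilibrium signal, arbitrary units
    dce_curve: DceCurve | None = None

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError(f"preset {self.name!r}: relaxation rates must be positive")
        self.adc_tensor = np.asarray(self.adc_tensor, dtype=float)
        if self.adc_tensor.shape != (3, 3):
            raise ValueError(f"preset {self.name!r}: adc_tensor must be 3x3")
        if not np.allclose(self.adc_tensor, self.adc_tensor.T):
            raise ValueError(f"preset {self.name!r}: adc_tensor must be symmetric")
        if np.linalg.eigvalsh(self.adc_tensor).min() < -1e-12:
            raise ValueError(f"preset {self.name!r}: adc_tensor must be positive semi-definite")
        if not 0.0 <= self.mtr <= 100.0:
            raise ValueError(f"preset {self.name!r}: MTR must be within [0, 100] percent")
        if self.s0 < 0:
            raise ValueError(f"preset {self.name!r}: s0 must be non-negative")

    @property
    def adc(self) -> float:
        """Mean diffusivity: one third of the tensor trace, um^2/ms."""
        return float(np.trace(self.adc_tensor) / 3.0)


def _iso(d: float) -> np.ndarray:
    return d * np.eye(3)


#: group-mean lesion parameter truths (R1 s^-1, R2 s^-1, ADC um^2/ms, MTR %,
#: target DCE AUC in the study's normalised per-second units) plus
#: literature-informed cortex/muscle values.
_TABLE = {
    # name:            r1,    r2,   adc,    mtr,  auc_target
    "tumor": (1.08, 14.9, 0.833, 24.1, 0.916),
    "rn": (1.26, 17.6, 0.736, 30.2, 0.784),
    "tumor_in_mixed": (1.05, 14.2, 0.872, 22.2, 1.22),
    "rn_in_mixed": (1.28, 17.7, 0.704, 29.0, 0.658),
    "cortex": (0.83, 20.0, 0.700, 30.5, 0.10),
    "muscle": (0.70, 25.0, 1.400, 40.0, None),
}

#: Table-style across-subject SDs for the lesion rows, used when drawing
#: per-subject presets for cohort statistics.
_TABLE_SD = {
    "tumor": (0.11, 0.87, 0.053, 1.5, 0.256),
    "rn": (0.09, 0.72, 0.052, 1.5, 0.247),
    "tumor_in_mixed": (0.06, 0.59, 0.042, 0.9, 0.37),
    "rn_in_mixed": (0.08, 1.16, 0.049, 1.6, 0.110),
    "cortex": (0.04, 0.8, 0.03, 1.0, 0.05),
    "muscle": (0.04, 1.0, 0.06, 1.5, 0.0),
}

#: muscle reference enhancement: ~40% peak enhancement reached within the
#: early post-injection window, no washout — this is the normaliser.
_MUSCLE_DCE = DceCurve(amplitude=0.4, onset_frame=30, k_up=0.05, k_wash=0.0)

#: lesion curve kinetics (amplitude calibrated against the AUC target).
_LESION_KINETICS = dict(onset_frame=30, k_up=0.02, k_wash=5e-4)


def _dce_frame_times(n_frames: int = 300, frame_dt: float = 3.0) -> np.ndarray:
    return np.arange(n_frames) * frame_dt


def calibrated_dce_amplitude(
    auc_target: float,
    kinetics: dict | None = None,
    muscle_curve: DceCurve = _MUSCLE_DCE,
    n_frames: int = 300,
    frame_dt: float = 3.0,
    early_frames: tuple[int, int] = (30, 120),
    injection_frame: int = 30,
) -> float:
    """Amplitude such that the noiseless AUC pipeline returns ``auc_target``.

    The AUC readout divides the muscle-normalised enhancement sum over the
    post-injection frames by (frame_dt x n_post); inverting that closed form
    for a given curve family fixes the amplitude.
    """
    kin = dict(_LESION_KINETICS, **(kinetics or {}))
    times = _dce_frame_times(n_frames, frame_dt)
    norm = muscle_curve.evaluate(times)[early_frames[0] : early_frames[1]].max()
    shape_sum = DceCurve(amplitude=1.0, **kin).shape(times)[injection_frame:].sum()
    n_post = n_frames - injection_frame
    if shape_sum <= 0:
        raise ValueError("enhancement curve integrates to zero; cannot calibrate")
    return auc_target * norm * frame_dt * n_post / shape_sum


def study_defaults() -> dict[str, TissuePreset]:
    """The default tissue-preset profile (group-mean truths)."""
    presets: dict[str, TissuePreset] = {}
    for name, (r1, r2, adc, mtr, auc) in _TABLE.items():
        if name == "muscle":
            curve = replace(_MUSCLE_DCE)
        elif auc is not None:
            curve = DceCurve(amplitude=calibrated_dce_amplitude(auc), **_LESION_KINETICS)
        else:
            curve = None
        presets[name] = TissuePreset(
            name=name, r1=r1, r2=r2, adc_tensor=_iso(adc), mtr=mtr, s0=100.0, dce_curve=curve
        )
    return presets


def subject_presets(rng: np.random.Generator) -> dict[str, TissuePreset]:
    """Draw one subject's tissue truths around the group means.

    Biological across-subject variation is modelled as independent Gaussian
    jitter with the tabulated SDs (truncated to keep parameters physical).
    """
    out: dict[str, TissuePreset] = {}
    for name, preset in study_defaults().items():
        sd = _TABLE_SD[name]
        r1 = max(rng.normal(preset.r1, sd[0]), 0.05)
        r2 = max(rng.normal(preset.r2, sd[1]), 0.5)
        adc = max(rng.normal(preset.adc, sd[2]), 0.05)
        mtr = float(np.clip(rng.normal(preset.mtr, sd[3]), 0.0, 100.0))
        curve = preset.dce_curve
        if curve is not None and name != "muscle" and sd[4] > 0:
            auc = max(rng.normal(_TABLE[name][4], sd[4]), 0.0)
            curve = DceCurve(amplitude=calibrated_dce_amplitude(auc), **_LESION_KINETICS)
        out[name] = TissuePreset(
            name=name, r1=r1, r2=r2, adc_tensor=_iso(adc), mtr=mtr, s0=preset.s0, dce_curve=curve
        )
    return out


# ---------------------------------------------------------------------------
# 2H spectroscopy kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticCurve:
    """Mono-exponential approach from baseline to plateau after onset (mM)."""

    baseline: float  # mM before onset
    plateau: float  # mM asymptote after onset
    rate: float = 0.12  # min^-1
    onset: float = 20.0  # min (infusion start; after two 10-min pre blocks)

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.plateau < 0:
            raise ValueError("concentrations must be non-negative")
        if self.rate <= 0:
            raise ValueError("kinetic rate must be positive")

    def __call__(self, t_min: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_min, dtype=float)
        c = self.baseline + (self.plateau - self.baseline) * (
            1.0 - np.exp(-self.rate * np.maximum(t - self.onset, 0.0))
        )
        return np.where(t < self.onset, self.baseline, c)


@dataclass
class DmrsKinetics:
    """Per-resonance spectral and kinetic truth for one cohort."""

    cohort: str  # control | tumor | rn
    curves: dict[str, KineticCurve]
    shifts_ppm: dict[str, float] = field(default_factory=lambda: dict(CHEMICAL_SHIFTS_PPM))
    r2star: dict[str, float] = field(
        default_factory=lambda: {"HOD": 15.0, "Glc": 25.0, "Lac": 30.0, "Glx": 30.0}
    )
    relaxation: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(RELAXATION_S))
    c_na: float = C_NA_MM

    def __post_init__(self) -> None:
        if self.cohort not in ("control", "tumor", "rn"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        hod = self.curves.get("HOD")
        if hod is None or abs(hod.baseline - self.c_na) > 1e-9:
            raise ValueError("HOD baseline must equal the natural-abundance concentration")
        for name, curve in self.curves.items():
            if name != "HOD" and curve.baseline != 0.0:
                raise ValueError(f"{name}: metabolites must start at zero before infusion")
        if self.cohort == "tumor":
            if not self.curves["Lac"].plateau > self.curves["Glx"].plateau:
                raise ValueError("tumor kinetics must have Lac plateau > Glx plateau")
        else:
            if not self.curves["Glx"].plateau > self.curves["Lac"].plateau:
                raise ValueError(f"{self.cohort} kinetics must have Glx plateau > Lac plateau")

    @property
    def resonances(self) -> list[str]:
        return list(self.curves)


#: cohort kinetic designs.  No absolute metabolite concentrations are
#: reported for this study design; plateaus are chosen to reproduce the
#: qualitative readout — tumors ferment glucose to lactate (Warburg effect:
#: Lac high, Glx low, terminal Glx:Lac < 1) while control and necrotic brain
#: oxidise it (Glx > Lac, ratio > 1), with roughly 5x dynamic range in
#: terminal lactate between tumor and control/rn.
_COHORT_PLATEAUS = {
    # cohort:   Glc,  Lac,  Glx   (mM)
    "control": (4.0, 1.0, 3.5),
    "tumor": (5.0, 6.0, 1.5),
    "rn": (4.0, 1.2, 3.2),
}


def cohort_kinetics(cohort: str, onset_min: float = 20.0) -> DmrsKinetics:
    """Default metabolite kinetics for one cohort."""
    if cohort not in _COHORT_PLATEAUS:
        raise ValueError(
            f"unknown cohort {cohort!r}; expected one of {tuple(_COHORT_PLATEAUS)}"
        )
    glc, lac, glx = _COHORT_PLATEAUS[cohort]
    curves = {
        # HOD rises slowly as label washes into body water
        "HOD": KineticCurve(baseline=C_NA_MM, plateau=C_NA_MM + 4.0, rate=0.03, onset=onset_min),
        "Glc": KineticCurve(baseline=0.0, plateau=glc, rate=0.25, onset=onset_min),
        "Lac": KineticCurve(baseline=0.0, plateau=lac, rate=0.10, onset=onset_min),
        "Glx": KineticCurve(baseline=0.0, plateau=glx, rate=0.08, onset=onset_min),
    }
    return DmrsKinetics(cohort=cohort, curves=curves)


# ---------------------------------------------------------------------------
# quantification configuration
# ---------------------------------------------------------------------------


@dataclass
class QuantConfig:
    """Constants of the absolute-quantification step.

    ``stoichiometry`` maps each resonance to effective surviving 2H labels
    per molecule; ``relaxation`` to published (T1, T2) in seconds.  The
    saturation correction assumes an ideal 90-degree excitation every TR.
    """

    stoichiometry: dict[str, float] = field(default_factory=lambda: dict(STOICHIOMETRY))
    relaxation: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(RELAXATION_S))
    tr: float = 0.45  # s
    te: float = 4.27e-3  # s
    c_na: float = C_NA_MM  # mM

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.stoichiometry.values()):
            raise ValueError("stoichiometries must be positive")
        if any(t1 <= 0 or t2 <= 0 for t1, t2 in self.relaxation.values()):
            raise ValueError("relaxation times must be positive")
        if self.c_na <= 0:
            raise ValueError("natural-abundance concentration must be positive")

    def correction_factor(self, resonance: str) -> float:
        """Multiplicative signal attenuation for one resonance.

        Detected amplitude = concentration-proportional amplitude times
        stoichiometry x (1 - exp(-TR/T1)) x exp(-TE/T2).
        """
        if resonance not in self.stoichiometry:
            raise KeyError(f"resonance {resonance!r} missing from stoichiometry map")
        if resonance not in self.relaxation:
            raise KeyError(f"resonance {resonance!r} missing from relaxation map")
        t1, t2 = self.relaxation[resonance]
        return (
            self.stoichiometry[resonance]
            * (1.0 - np.exp(-self.tr / t1))
            * np.exp(-self.te / t2)
        )
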