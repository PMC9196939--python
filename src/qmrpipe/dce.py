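"""Semi-quantitative DCE-MRI area-under-curve mapping.

The readout is deliberately model-free: per-voxel fractional enhancement
relative to the pre-contrast baseline, normalised by the peak early
enhancement of reference muscle (to absorb contrast-delivery variation),
summed over the post-injection frames and divided by the post-injection
duration.  With the default 300-frame / 3-s protocol and injection at
frame 30 the divisor is 3 s x 270 frames = 810 s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .containers import ImageStack, ParametricMap


@dataclass
class DceSeries:
    """A DCE time series with its frame-window conventions.

    Frame windows use 0-based indices: baseline frames 0..29 (1-based display
    frame numbers 1-30), early muscle window 30..119 (numbers 31-120),
    injection at frame index 30.
    """

    stack: ImageStack
    muscle_mask: np.ndarray
    baseline_frames: tuple[int, int] = (0, 30)  # half-open [start, stop)
    early_frames: tuple[int, int] = (30, 120)
    injection_frame: int = 30
    frame_dt: float = 3.0  # s
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stack.data.ndim != 4:
            raise ValueError("DCE stack must be 4-D (x, y, z, frame)")
        n = self.stack.n_volumes
        b0, b1 = self.baseline_frames
        e0, e1 = self.early_frames
        if not (0 <= b0 < b1 <= e0 < e1 <= n):
            raise ValueError(
                "frame windows must satisfy baseline < early within the series "
                f"(got baseline {self.baseline_frames}, early {self.early_frames}, n={n})"
            )
        if b1 - b0 < 2:
            raise ValueError("need at least 2 baseline frames")
        if not (0 < self.injection_frame < n):
            raise ValueError("injection frame must lie inside the series")
        self.muscle_mask = np.asarray(self.muscle_mask, dtype=bool)
        if self.muscle_mask.shape != self.stack.shape3d:
            raise ValueError("muscle mask must match the image grid")
        if not self.muscle_mask.any():
            raise ValueError("muscle mask is empty")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    @property
    def n_post(self) -> int:
        return self.stack.n_volumes - self.injection_frame

    @property
    def divisor_s(self) -> float:
        """Post-injection duration in seconds (810 s under the defaults)."""
        return self.frame_dt * self.n_post


def fractional_enhancement(series: DceSeries, baseline_floor: float = 1e-9) -> ImageStack:
    """FE(v, t) = (S(v, t) - baseline(v)) / baseline(v).

    The baseline is the mean over the pre-contrast frames.  Voxels whose
    baseline is at or below ``baseline_floor`` (relative to the series peak)
    are masked out and counted in the output metadata — a zero baseline has
    no meaningful enhancement.
    """
    data = series.stack.data.astype(float)
    b0, b1 = series.baseline_frames
    base = data[..., b0:b1].mean(axis=-1)
    floor = baseline_floor * max(float(data.max()), 1.0)
    valid = base > floor
    fe = np.full_like(data, np.nan)
    np.divide(data - base[..., None], base[..., None], out=fe, where=valid[..., None])
    meta = dict(series.stack.meta)
    meta.update(valid_mask=valid, n_masked_baseline=int((~valid).sum()), kind="fractional_enhancement")
    return ImageStack(data=fe, voxel_size=series.stack.voxel_size, axis="frame", meta=meta)


def muscle_norm_factor(fe: ImageStack, series: DceSeries) -> float:
    """Peak early-window enhancement of the muscle ROI-mean time course.

    The muscle ROI is averaged first and the maximum taken over the early
    frames second (max of the mean curve, not mean of voxel maxima).
    """
    valid = fe.meta.get("valid_mask", np.ones(fe.shape3d, dtype=bool))
    sel = series.muscle_mask & valid
    if not sel.any():
        raise ValueError("muscle mask contains no valid (baseline-positive) voxels")
    curve = fe.data[sel].mean(axis=0)
    e0, e1 = series.early_frames
    factor = float(np.nanmax(curve[e0:e1]))
    if not factor > 0:
        raise ValueError(
            f"muscle normalisation factor {factor:.4g} is not positive: "
            "no contrast arrival detected in the reference muscle"
        )
    return factor


def compute_auc(fe: ImageStack, norm: float, series: DceSeries) -> ParametricMap:
    """AUC(v) = sum over post-injection frames of FE/norm, over frame_dt x n_post.

    Units are per-second of normalised enhancement (reported as 'au').
    """
    if not norm > 0:
        raise ValueError("normalisation factor must be positive")
    post = fe.data[..., series.injection_frame :]
    auc = post.sum(axis=-1) / norm / series.divisor_s
    valid = fe.meta.get("valid_mask", np.ones(fe.shape3d, dtype=bool))
    report = {"n_fitted": int(valid.sum()), "n_masked_baseline": int((~valid).sum())}
    return ParametricMap(
        values=np.where(valid, auc, np.nan),
        uncertainty=np.zeros_like(auc),
        mask=valid,
        param="DCE_AUC",
        units="au",
        meta={
            "model": "dce_auc",
            "norm_factor": norm,
            "divisor_s": series.divisor_s,
            "injection_frame": series.injection_frame,
        },
        report=report,
    )


def dce_auc_pipeline(series: DceSeries) -> tuple[ParametricMap, float]:
    """Fractional enhancement -> muscle normalisation -> AUC map."""
    fe = fractional_enhancement(series)
    norm = muscle_norm_factor(fe, series)
    return compute_auc(fe, norm, series), norm
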