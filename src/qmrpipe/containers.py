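"""In-memory containers shared across the pipeline stages.

The pipeline moves three kinds of data around: multi-volume image stacks
(one volume per flip angle / echo / diffusion direction / MT state / time
frame), voxelwise parametric maps with their uncertainties and fit masks,
and complex time-domain spectroscopy records acquired in signal-averaged
blocks.  Each container carries enough geometry/acquisition metadata to be
written to and recovered from disk losslessly (see :mod:`qmrpipe.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: recognised meanings of the 4th (acquisition) axis of an ImageStack
AXIS_KINDS = ("flip_angle", "echo", "diffusion", "mt_state", "frame", "none")


@dataclass
class ImageStack:
    """A 3-D or 4-D voxel array with geometry and acquisition-axis labels.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)`` or ``(nx, ny, nz, nvol)``.
    voxel_size:
        In-plane and through-plane voxel dimensions in millimetres.
    axis:
        Meaning of the 4th axis; one of :data:`AXIS_KINDS`.
    meta:
        Free-form acquisition provenance (flip angles, echo times, ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    axis: str = "none"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"ImageStack data must be 3-D or 4-D, got {self.data.ndim}-D")
        if self.axis not in AXIS_KINDS:
            raise ValueError(f"unknown axis kind {self.axis!r}; expected one of {AXIS_KINDS}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")

    @property
    def n_volumes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ParametricMap:
    """A fitted voxelwise parameter map.

    ``values`` holds the parameter estimate, ``uncertainty`` its 1-sigma
    fit uncertainty, and ``mask`` flags voxels where the fit succeeded.
    Voxels outside ``mask`` were never fitted or failed QC; they are
    flagged, not silently zeroed, and per-reason counts live in ``report``.
    """

    values: np.ndarray
    uncertainty: np.ndarray
    mask: np.ndarray
    param: str
    units: str
    meta: dict[str, Any] = field(default_factory=dict)
    report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.values.shape == self.uncertainty.shape == self.mask.shape):
            raise ValueError("values, uncertainty and mask must share a shape")

    def roi_mean(self, roi: np.ndarray) -> float:
        """Mean over the intersection of an ROI with the fitted mask."""
        sel = np.asarray(roi, dtype=bool) & self.mask
        if not sel.any():
            raise ValueError("ROI does not intersect the fitted region")
        return float(self.values[sel].mean())


@dataclass
class FIDSeries:
    """Complex time-domain records, one row per signal-averaged block.

    Attributes
    ----------
    data:
        Complex array ``(n_blocks, n_points)``.
    dwell:
        Sampling interval in seconds (inverse acquisition bandwidth).
    f0_mhz:
        Observe frequency in MHz (sets the Hz-per-ppm scale).
    ppm_ref:
        Chemical shift (ppm) of the receiver reference (carrier) frequency.
    block_times:
        Start time of each block in minutes from the start of the study.
    """

    data: np.ndarray
    dwell: float
    f0_mhz: float
    ppm_ref: float
    block_times: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("FID data must be (n_blocks, n_points)")
        if self.dwell <= 0:
            raise ValueError("dwell time must be positive")
        self.block_times = np.asarray(self.block_times, dtype=float)
        if self.block_times.shape != (self.data.shape[0],):
            raise ValueError("block_times must have one entry per block")

    @property
    def n_blocks(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times within one FID, seconds."""
        return np.arange(self.n_points) * self.dwell

    def hz_per_ppm(self) -> float:
        return self.f0_mhz  # 1 ppm at f0 MHz is f0 Hz


@dataclass
class TitrationSeries:
    """Standard-addition titration: signal amplitude vs added analyte."""

    deltas: np.ndarray  # added HOD above natural abundance, mM
    amplitudes: np.ndarray  # detected signal amplitude, arbitrary units
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.deltas.shape != self.amplitudes.shape:
            raise ValueError("deltas and amplitudes must align")
        if np.any(self.deltas < 0):
            raise ValueError("added concentrations must be non-negative")
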