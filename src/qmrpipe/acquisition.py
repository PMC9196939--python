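"""Acquisition specifications for every sequence the pipeline simulates/fits.

Defaults reproduce the small-animal protocol the pipeline was designed
around: 4.7-T multi-contrast imaging (VFA gradient echo, 16-echo spin echo,
6-direction DWI, MT on/off pair, 300-frame DCE) and 11.74-T single-voxel
deuterium spectroscopy in 10-minute signal-averaged blocks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

SEQUENCES = ("vfa", "mems", "dwi", "mt", "dce", "dmrs")


@dataclass
class AcquisitionSpec:
    """Per-sequence timing and encoding parameters.

    Only the fields relevant to ``sequence`` need to be populated; the
    validator enforces the ones each sequence requires.
    """

    sequence: str
    tr: float = 0.0  # s
    te: float | None = None  # s (single-echo sequences)
    te_list: np.ndarray | None = None  # s (multi-echo)
    flip_angles_deg: np.ndarray | None = None  # degrees (vfa)
    b_matrices: np.ndarray | None = None  # (nvol, 3, 3) s/mm^2, incl. b~0
    mt_states: tuple[str, ...] = ("off", "on")
    mt_offset_hz: float | None = None
    n_frames: int | None = None  # dce
    frame_dt: float | None = None  # s per frame (dce)
    dwell: float | None = None  # s (dmrs)
    n_points: int | None = None  # complex points per FID (dmrs)
    block_duration_min: float | None = None  # dmrs block length, minutes
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ValueError(f"unknown sequence {self.sequence!r}; expected one of {SEQUENCES}")
        if self.tr < 0:
            raise ValueError("TR must be non-negative")
        if self.flip_angles_deg is not None:
            self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
        if self.te_list is not None:
            self.te_list = np.asarray(self.te_list, dtype=float)
            if np.any(self.te_list <= 0):
                raise ValueError("echo times must be positive")
        if self.b_matrices is not None:
            self.b_matrices = np.asarray(self.b_matrices, dtype=float)
            if self.b_matrices.ndim != 3 or self.b_matrices.shape[1:] != (3, 3):
                raise ValueError("b_matrices must be (nvol, 3, 3)")
        if self.sequence == "vfa" and (self.flip_angles_deg is None or self.tr <= 0):
            raise ValueError("vfa requires flip_angles_deg and TR > 0")
        if self.sequence == "mems" and self.te_list is None:
            raise ValueError("mems requires te_list")
        if self.sequence == "dwi":
            if self.b_matrices is None:
                raise ValueError("dwi requires b_matrices")
            traces = np.trace(self.b_matrices, axis1=1, axis2=2)
            if traces.min() > 50.0:
                raise ValueError("dwi b_matrices must include one b~0 acquisition")
        if self.sequence == "dce":
            if not self.n_frames or not self.frame_dt or self.frame_dt <= 0:
                raise ValueError("dce requires n_frames and frame_dt > 0")
        if self.sequence == "dmrs":
            if not self.dwell or not self.n_points or not self.block_duration_min:
                raise ValueError("dmrs requires dwell, n_points and block_duration_min")
            if self.dwell <= 0 or self.block_duration_min <= 0:
                raise ValueError("dmrs timing must be positive")

    @property
    def n_volumes(self) -> int:
        if self.sequence == "vfa":
            return len(self.flip_angles_deg)
        if self.sequence == "mems":
            return len(self.te_list)
        if self.sequence == "dwi":
            return len(self.b_matrices)
        if self.sequence == "mt":
            return len(self.mt_states)
        if self.sequence == "dce":
            return int(self.n_frames)
        raise ValueError("dmrs acquisitions have no image volumes")


def six_direction_bmatrices(b_max: float = 1000.0) -> np.ndarray:
    """One b~0 volume plus a standard 6-direction dual-gradient scheme.

    Directions (1,1,0)/sqrt2 and permutations/sign-flips span the six unique
    elements of a symmetric tensor; the b-matrix of each volume is
    ``b * g g^T`` in s/mm^2.
    """
    dirs = np.array(
        [
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
            [1, -1, 0],
            [1, 0, -1],
            [0, 1, -1],
        ],
        dtype=float,
    )
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    mats = [np.zeros((3, 3))]
    for g in dirs:
        mats.append(b_max * np.outer(g, g))
    return np.stack(mats)


def default_vfa() -> AcquisitionSpec:
    """Gradient-echo VFA: TR 0.1 s, TE 1.6 ms, six flip angles 5-70 deg."""
    return AcquisitionSpec(
        sequence="vfa",
        tr=0.1,
        te=1.6e-3,
        flip_angles_deg=np.array([5.0, 10.0, 15.0, 30.0, 50.0, 70.0]),
    )


def default_mems() -> AcquisitionSpec:
    """Multi-echo spin echo: TR 6 s, 16 echoes at 11-ms spacing."""
    return AcquisitionSpec(
        sequence="mems",
        tr=6.0,
        te_list=11e-3 * np.arange(1, 17),
    )


def default_dwi(b_max: float = 1000.0) -> AcquisitionSpec:
    """Six-direction DWI with max b 1,000 s/mm^2 plus one b~0 volume."""
    return AcquisitionSpec(
        sequence="dwi",
        tr=1.5,
        te=30e-3,
        b_matrices=six_direction_bmatrices(b_max),
    )


def default_mt() -> AcquisitionSpec:
    """MT on/off pair; saturation offset 2,000 Hz (10 ppm) from water."""
    return AcquisitionSpec(
        sequence="mt",
        tr=2.0,
        te=6.5e-3,
        mt_states=("off", "on"),
        mt_offset_hz=2000.0,
    )


def default_dce() -> AcquisitionSpec:
    """DCE time series: 300 frames at 3-s resolution."""
    return AcquisitionSpec(
        sequence="dce",
        tr=47e-3,
        te=1.6e-3,
        n_frames=300,
        frame_dt=3.0,
    )


def default_dmrs() -> AcquisitionSpec:
    """Single-voxel 2H spectroscopy: TR 450 ms, TE 4.27 ms, 1,024 complex
    points at 1,500-Hz bandwidth, nominal 10-min signal-averaged blocks."""
    return AcquisitionSpec(
        sequence="dmrs",
        tr=0.45,
        te=4.27e-3,
        dwell=1.0 / 1500.0,
        n_points=1024,
        block_duration_min=10.0,
    )


DEFAULT_FACTORIES = {
    "vfa": default_vfa,
    "mems": default_mems,
    "dwi": default_dwi,
    "mt": default_mt,
    "dce": default_dce,
    "dmrs": default_dmrs,
}
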