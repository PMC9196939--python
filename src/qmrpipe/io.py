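"""Standard-format I/O: NIfTI-1 + JSON sidecars, HDF5 FID containers.

Image stacks and parametric maps travel as NIfTI-1 with a JSON sidecar
carrying the acquisition axis meaning and per-sequence parameters (flip
angles, echo times, b-matrices as row-major 3x3 lists in s/mm^2, frame
times).  FID series travel as HDF5 with native complex arrays plus a JSON
metadata mirror.  Write-then-read is bit-exact for data and declared
metadata.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .containers import FIDSeries, ImageStack, ParametricMap

SCHEMA_VERSION = "1"


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def save_stack(stack: ImageStack, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(stack.data.astype(np.float64), _affine(stack.voxel_size))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    meta = {k: v for k, v in stack.meta.items() if not isinstance(v, np.ndarray)}
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "image_stack",
        "axis": stack.axis,
        "voxel_size_mm": list(stack.voxel_size),
        "meta": _jsonable(meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_stack(path: "str | Path") -> ImageStack:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        if sidecar.get("kind") not in ("image_stack", "parametric_map"):
            raise ValueError(
                f"unknown sidecar dialect {sidecar.get('kind')!r}; "
                f"expected schema version {SCHEMA_VERSION} image_stack"
            )
        axis = sidecar.get("axis", "none")
        voxel = tuple(sidecar.get("voxel_size_mm"))
        meta = sidecar.get("meta", {})
    else:
        axis = "none"
        voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
        meta = {}
    return ImageStack(data=data, voxel_size=voxel, axis=axis, meta=meta)


# ---------------------------------------------------------------------------
# parametric maps
# ---------------------------------------------------------------------------


def save_map(pmap: ParametricMap, path: "str | Path", voxel_size=(0.25, 0.25, 0.5)) -> Path:
    """Write a map as a 4-D NIfTI [value, uncertainty, mask] + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack(
        [pmap.values, pmap.uncertainty, pmap.mask.astype(np.float64)], axis=-1
    )
    img = nib.Nifti1Image(data.astype(np.float64), _affine(voxel_size))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    meta = {k: v for k, v in pmap.meta.items() if not isinstance(v, np.ndarray)}
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "parametric_map",
        "param": pmap.param,
        "units": pmap.units,
        "volumes": ["value", "uncertainty", "mask"],
        "report": pmap.report,
        "meta": _jsonable(meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_map(path: "str | Path") -> ParametricMap:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    sidecar = json.loads(_sidecar_path(path).read_text())
    if sidecar.get("kind") != "parametric_map":
        raise ValueError(
            f"unknown sidecar dialect {sidecar.get('kind')!r}; expected parametric_map "
            f"schema version {SCHEMA_VERSION}"
        )
    return ParametricMap(
        values=data[..., 0],
        uncertainty=data[..., 1],
        mask=data[..., 2] > 0.5,
        param=sidecar["param"],
        units=sidecar["units"],
        meta=sidecar.get("meta", {}),
        report={k: int(v) for k, v in sidecar.get("report", {}).items()},
    )


def save_labels(label_map: np.ndarray, voxel_size, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(label_map, dtype=np.int16), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_labels(path: "str | Path") -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.int16)


# ---------------------------------------------------------------------------
# FID series
# ---------------------------------------------------------------------------


def save_fids(fids: FIDSeries, path: "str | Path") -> Path:
    """HDF5 container: complex data [block, point] + acquisition attrs,
    with a JSON metadata mirror next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=fids.data)
        f.create_dataset("block_times_min", data=fids.block_times)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["dwell_s"] = fids.dwell
        f.attrs["f0_mhz"] = fids.f0_mhz
        f.attrs["ppm_ref"] = fids.ppm_ref
        f.attrs["meta_json"] = json.dumps(_jsonable(fids.meta))
    mirror = {
        "schema_version": SCHEMA_VERSION,
        "kind": "fid_series",
        "n_blocks": fids.n_blocks,
        "n_points": fids.n_points,
        "dwell_s": fids.dwell,
        "f0_mhz": fids.f0_mhz,
        "ppm_ref": fids.ppm_ref,
        "block_times_min": fids.block_times.tolist(),
        "meta": _jsonable(fids.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(mirror, indent=1))
    return path


def load_fids(path: "str | Path") -> FIDSeries:
    with h5py.File(path, "r") as f:
        if str(f.attrs.get("schema_version", "")) != SCHEMA_VERSION:
            raise ValueError(
                f"unknown FID container schema {f.attrs.get('schema_version')!r}; "
                f"expected {SCHEMA_VERSION}"
            )
        return FIDSeries(
            data=f["data"][()],
            dwell=float(f.attrs["dwell_s"]),
            f0_mhz=float(f.attrs["f0_mhz"]),
            ppm_ref=float(f.attrs["ppm_ref"]),
            block_times=f["block_times_min"][()],
            meta=json.loads(f.attrs["meta_json"]),
        )


# ---------------------------------------------------------------------------
# tabular
# ---------------------------------------------------------------------------


def read_manifest(path: "str | Path") -> pd.DataFrame:
    """Read a cohort manifest CSV, tolerating BOM and CRLF line endings."""
    return pd.read_csv(path, encoding="utf-8-sig")


def write_ground_truth(rows: list[dict], path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
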