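"""Format readers and writers: NIfTI series with JSON sidecars, masks, and
the CSV dialects used between pipeline stages.

A dynamic series is stored as a 4-D NIfTI-1 file (x, y, 1, time) plus a
JSON sidecar ``<stem>.json`` carrying per-frame trigger times (ms) and
frame roles (``pd`` / ``imaging``), and optionally the low-resolution AIF
signal series.  DICOM directories are supported when pydicom is installed;
it is an optional dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "write_series",
    "read_series",
    "write_mask",
    "read_mask",
    "write_curve_csv",
    "read_curve_csv",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(path, frames: np.ndarray, times_ms, roles,
                 aif_signals=None, pixel_spacing=(1.5, 1.5)) -> Path:
    """Write a dynamic series as 4-D NIfTI + JSON sidecar.

    ``frames`` is (n_frames, ny, nx); stored as float32, time on the last
    axis.  ``roles`` is one of ``pd``/``imaging``/``aif`` per frame.
    """
    path = Path(path)
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, ny, nx)")
    if len(times_ms) != len(frames) or len(roles) != len(frames):
        raise ValueError("times_ms and roles must match the frame count")
    data = np.transpose(frames, (2, 1, 0))[:, :, np.newaxis, :]  # x,y,z,t
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    nib.save(img, str(path))
    sidecar = {
        "frame_times_ms": [float(t) for t in times_ms],
        "frame_roles": list(roles),
    }
    if aif_signals is not None:
        sidecar["aif_signals"] = [float(v) for v in aif_signals]
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path):
    """Read a series written by :func:`write_series`.

    Returns ``(frames, times_ms, roles, aif_signals)`` with frames as
    (n_frames, ny, nx) float32; ``aif_signals`` is None when absent.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame_times_ms", "frame_roles"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required key {key!r}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D series, got shape {data.shape}")
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0))
    times = np.asarray(meta["frame_times_ms"], dtype=float)
    roles = list(meta["frame_roles"])
    if len(times) != len(frames):
        raise ValueError("sidecar frame count does not match the image")
    aif = meta.get("aif_signals")
    aif = np.asarray(aif, dtype=float) if aif is not None else None
    return frames, times, roles, aif


def _read_dicom_series(directory: Path):
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading DICOM directories requires the optional pydicom "
            "dependency; install pydicom or convert to NIfTI + sidecar"
        ) from exc
    records = []
    for f in sorted(directory.iterdir()):
        if f.is_file():
            try:
                ds = pydicom.dcmread(str(f))
            except Exception:
                continue
            trigger = float(getattr(ds, "TriggerTime", 0.0))
            records.append((trigger, ds.pixel_array.astype(np.float32)))
    if not records:
        raise ValueError(f"no readable DICOM frames in {directory}")
    records.sort(key=lambda r: r[0])
    times = np.array([r[0] for r in records])
    frames = np.stack([r[1] for r in records])
    roles = ["imaging"] * len(frames)
    return frames, times, roles, None


def write_mask(path, mask: np.ndarray, pixel_spacing=(1.5, 1.5)) -> Path:
    path = Path(path)
    mask = np.asarray(mask).astype(np.uint8)
    data = mask.T[:, :, np.newaxis]
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    return data.T.astype(bool)


def write_curve_csv(path, curve) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": curve.times, "conc_mmol_per_L": curve.values}
                 ).to_csv(path, index=False)
    return path


def read_curve_csv(path, kind: str = "tissue"):
    from perfquant.perfusion import ConcentrationCurve

    df = pd.read_csv(path)
    return ConcentrationCurve(times=df["time_s"].to_numpy(),
                              values=df["conc_mmol_per_L"].to_numpy(),
                              kind=kind)
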