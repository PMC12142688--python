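"""NIfTI / text I/O for the pipeline's file-based stage handoffs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fiber_dti import DtiVolume
from .phantom import ForceTrace
from .preproc import VelocitySeries

__all__ = [
    "affine_from_spacing",
    "save_volume",
    "load_volume",
    "save_velocity_series",
    "load_velocity_series",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_dwi",
    "load_dwi",
    "save_force_trace",
    "load_force_trace",
]


def affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path, data: np.ndarray, spacing, descrip: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(data), affine_from_spacing(spacing))
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), spacing


def save_velocity_series(directory, series: VelocitySeries) -> None:
    """Write phase (5D: x,y,z,frame,component), velocity and magnitude NIfTIs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # (frame, comp, x, y, z) -> (x, y, z, frame, comp)
    phase = np.transpose(series.phase, (2, 3, 4, 0, 1))
    save_volume(directory / "phase.nii.gz", phase, series.spacing,
                descrip="phase [rad]")
    vel = np.transpose(series.velocity, (2, 3, 4, 0, 1))
    save_volume(directory / "velocity.nii.gz", vel, series.spacing,
                descrip="velocity [cm/s]")
    mag = np.transpose(series.magnitude, (1, 2, 3, 0))
    save_volume(directory / "magnitude.nii.gz", mag, series.spacing)
    meta = pd.Series(
        {"venc": series.venc, "frame_dt": series.frame_dt,
         "n_frames": series.n_frames}
    )
    meta.to_json(directory / "series.json")


def load_velocity_series(directory) -> VelocitySeries:
    directory = Path(directory)
    phase, spacing = load_volume(directory / "phase.nii.gz")
    mag, _ = load_volume(directory / "magnitude.nii.gz")
    meta = pd.read_json(directory / "series.json", typ="series")
    series = VelocitySeries(
        phase=np.transpose(phase, (3, 4, 0, 1, 2)),
        magnitude=np.transpose(mag, (3, 0, 1, 2)),
        venc=float(meta["venc"]),
        spacing=spacing,
        frame_dt=float(meta["frame_dt"]),
    )
    vel_path = directory / "velocity.nii.gz"
    if vel_path.exists():
        vel, _ = load_volume(vel_path)
        series = series.with_velocity(np.transpose(vel, (3, 4, 0, 1, 2)))
    return series


def save_bvals_bvecs(prefix, b_values: np.ndarray, b_vectors: np.ndarray) -> None:
    """FSL-style text files: one row of b-values; three rows of components."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), np.atleast_2d(b_values), fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), np.asarray(b_vectors).T, fmt="%.8f")


def load_bvals_bvecs(prefix) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).T
    return bvals, bvecs


def save_dwi(directory, dwi: DtiVolume) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.transpose(dwi.signals, (1, 2, 3, 0))
    save_volume(directory / "dwi.nii.gz", stack, (1.875, 1.875, 5.0))
    save_volume(directory / "dwi_mask.nii.gz", dwi.mask.astype(np.uint8),
                (1.875, 1.875, 5.0))
    save_bvals_bvecs(directory / "dwi", dwi.b_values, dwi.b_vectors)


def load_dwi(directory) -> DtiVolume:
    directory = Path(directory)
    stack, _ = load_volume(directory / "dwi.nii.gz")
    mask, _ = load_volume(directory / "dwi_mask.nii.gz")
    bvals, bvecs = load_bvals_bvecs(directory / "dwi")
    return DtiVolume(
        signals=np.transpose(stack, (3, 0, 1, 2)),
        b_values=bvals,
        b_vectors=bvecs,
        mask=mask.astype(bool),
    )


def save_force_trace(path, force: ForceTrace) -> None:
    df = pd.DataFrame({"frame": np.arange(force.n_frames),
                       "force": force.values})
    header = f"# pct_mvc={force.pct_mvc},peak_frame={force.peak_frame}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def load_force_trace(path) -> ForceTrace:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split(","))
        df = pd.read_csv(fh)
    return ForceTrace(
        values=df["force"].to_numpy(),
        pct_mvc=float(meta["pct_mvc"]),
        peak_frame=int(meta["peak_frame"]),
    )
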