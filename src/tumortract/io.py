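"""File I/O: NIfTI volumes, FSL bvals/bvecs, TRK/TCK tractograms, CSV tables.

All readers and writers delegate to nibabel and pandas; this module only
adapts between the on-disk formats and the package's in-memory containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import streamlines as nib_streamlines

from .phantom import DwiVolume, GradientTable
from .tracking import Streamline, Tractogram

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_dwi",
    "load_dwi",
    "save_tractogram",
    "load_tractogram",
    "save_table",
    "load_table",
    "save_params",
]


def save_nifti(path, data: np.ndarray, affine: np.ndarray, dtype=None) -> None:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine)), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_bvals_bvecs(prefix, gtab: GradientTable) -> tuple[Path, Path]:
    """FSL convention: one row of b-values; three rows of direction
    components."""
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    np.savetxt(bval_path, gtab.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.directions.T, fmt="%.9g")
    return bval_path, bvec_path


def load_bvals_bvecs(bval_path, bvec_path) -> GradientTable:
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    b0 = bvals <= 1e-6
    return GradientTable(directions=bvecs, bvalues=bvals, b0_flags=b0)


def save_dwi(out_dir, name: str, dwi: DwiVolume) -> dict:
    """Write a DWI volume as NIfTI + bvals/bvecs; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nii = out_dir / f"{name}.nii.gz"
    save_nifti(nii, dwi.signal, dwi.affine, dtype=np.float32)
    bval, bvec = save_bvals_bvecs(out_dir / name, dwi.gradient_table)
    return {"dwi": str(nii), "bval": str(bval), "bvec": str(bvec)}


def load_dwi(nii_path, bval_path, bvec_path) -> DwiVolume:
    data, affine = load_nifti(nii_path)
    gtab = load_bvals_bvecs(bval_path, bvec_path)
    voxel_size = tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return DwiVolume(signal=np.asarray(data, dtype=np.float64),
                     voxel_size=voxel_size, affine=affine, gradient_table=gtab)


def save_peaks(out_dir, peaks) -> dict:
    """Write a peak field as a 5D NIfTI (x, y, z, peak, component) plus a
    QA companion volume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = peaks.affine if peaks.affine is not None else np.eye(4)
    dirs_path = out_dir / "peaks.nii.gz"
    qa_path = out_dir / "qa.nii.gz"
    save_nifti(dirs_path, peaks.directions, aff, dtype=np.float32)
    save_nifti(qa_path, peaks.qa, aff, dtype=np.float32)
    save_params(out_dir / "peaks.json",
                {"voxel_size": list(peaks.voxel_size)})
    return {"peaks": str(dirs_path), "qa": str(qa_path)}


def load_peaks(peaks_dir):
    from .recon import PeakField

    peaks_dir = Path(peaks_dir)
    dirs, aff = load_nifti(peaks_dir / "peaks.nii.gz")
    qa, _ = load_nifti(peaks_dir / "qa.nii.gz")
    with open(peaks_dir / "peaks.json") as fh:
        meta = json.load(fh)
    dirs = np.asarray(dirs, dtype=np.float64)
    qa = np.asarray(qa, dtype=np.float64)
    return PeakField(directions=dirs, qa=qa,
                     n_peaks=(qa > 0).sum(axis=-1).astype(np.int32),
                     voxel_size=tuple(meta["voxel_size"]), affine=aff)


def load_gene_sets(gmt_path) -> dict:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(gmt_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def save_tractogram(path, tractogram: Tractogram, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write TRK or TCK (chosen by extension) in world (RAS mm) coordinates."""
    path = Path(path)
    sl = [s.points for s in tractogram.streamlines]
    t = nib_streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = {
            "voxel_sizes": np.asarray(voxel_size, dtype=np.float32),
            "voxel_to_rasmm": np.asarray(tractogram.affine, dtype=np.float32),
            "voxel_order": "RAS",
        }
        nib_streamlines.save(t, str(path), header=header)
    elif path.suffix == ".tck":
        nib_streamlines.save(t, str(path))
    else:
        raise ValueError(f"unsupported tractogram extension: {path.suffix}")


def load_tractogram(path, affine: np.ndarray | None = None) -> Tractogram:
    tfile = nib_streamlines.load(str(path))
    sl = [Streamline(points=np.asarray(pts, dtype=np.float64))
          for pts in tfile.tractogram.streamlines]
    if affine is None:
        hdr = tfile.header
        affine = np.asarray(hdr.get("voxel_to_rasmm", np.eye(4)), dtype=np.float64)
        if not np.isfinite(affine).all() or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            affine = np.eye(4)
    return Tractogram(streamlines=sl, affine=np.asarray(affine))


def save_table(path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, index=index)


def load_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def save_params(path, params: dict) -> None:
    """Echo generation parameters to a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
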