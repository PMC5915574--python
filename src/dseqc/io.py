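"""File input/output: NIfTI and matrix readers, TSV/JSON writers.

Internal layout is always voxels x time.  4D volumes are flattened in
x-fastest (Fortran) order so voxel row i maps back to a unique location in
the original geometry, which is retained for writing maps out.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DSEImages, DSETimeSeries, RawData

__all__ = [
    "RunConfig",
    "read_nifti_4d",
    "read_matrix",
    "read_input",
    "write_dse_timeseries_tsv",
    "write_dse_images_nifti",
    "write_null_model_json",
    "write_provenance",
]


@dataclass
class RunConfig:
    """Parameters of a single QC run (one dataset end to end)."""

    input_path: str
    mask_path: str | None = None
    scale_mode: str = "median-of-means"
    target: float = 100.0
    mu0_method: str = "median_dvars2"
    var_method: str = "hiqr"
    d: float = 1.0 / 3.0
    alpha: float = 0.05
    correction: str = "bonferroni"
    delta_threshold: float = 5.0
    two_sided: bool = False
    output_dir: str = "."
    seed: int | None = None
    plot: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def read_nifti_4d(path, mask_path=None) -> RawData:
    """Load a 4D NIfTI volume (optionally masked) as a voxels x time matrix.

    Parameters
    ----------
    path : str or Path
        4D NIfTI-1/NIfTI-2 image.
    mask_path : str or Path, optional
        3D mask image; nonzero voxels are retained.  Must match the spatial
        dimensions of the data.

    Raises
    ------
    ValueError
        For non-4D input or a mask whose shape does not match.
    """
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel message passthrough
        raise ValueError(f"unreadable image {path}: {exc}") from exc
    if img.ndim != 4:
        raise ValueError(f"not a 4D image: {path} has shape {img.shape}")
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    shape3 = data.shape[:3]

    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if tuple(mimg.shape[:3]) != tuple(shape3):
            raise ValueError(
                f"mask shape {mimg.shape[:3]} does not match data {shape3}"
            )
        mask = np.asanyarray(mimg.dataobj) != 0
    else:
        mask = np.ones(shape3, dtype=bool)

    flat = data.reshape(-1, data.shape[3], order="F")
    ids = np.flatnonzero(mask.reshape(-1, order="F"))
    geometry = {"shape": shape3, "affine": img.affine, "header": img.header}
    return RawData(values=flat[ids], voxel_ids=ids, geometry=geometry)


def read_matrix(path) -> RawData:
    """Load an I x T matrix from delimited text (.tsv/.csv/.txt) or .npy."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        delim = "," if path.suffix == ".csv" else None
        values = np.loadtxt(path, delimiter=delim)
    if values.ndim == 1:
        values = values[None, :]
    return RawData(values=values)


def read_input(path, mask_path=None) -> RawData:
    """Dispatch on extension: NIfTI for .nii/.nii.gz, matrix otherwise."""
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return read_nifti_4d(path, mask_path=mask_path)
    if mask_path is not None:
        raise ValueError("mask is only supported for NIfTI input")
    return read_matrix(path)


def write_dse_timeseries_tsv(dse: DSETimeSeries, path) -> None:
    """Tidy long-format table of all 12 series.

    Columns: index (1-based), abscissa (t for A/E, t + 1/2 for D/S),
    component, scope, value.
    """
    frames = []
    for scope in ("whole", "global", "nonglobal"):
        for comp in "ADSE":
            series = dse.series(comp, scope)
            absc = dse.abscissa(comp)
            frames.append(pd.DataFrame({
                "index": np.arange(1, len(series) + 1),
                "abscissa": absc,
                "component": comp,
                "scope": scope,
                "value": series,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.10g")


def write_dse_images_nifti(images: DSEImages, out_dir, prefix: str = "dse") -> dict[str, Path]:
    """Write A/D/S maps back into the input geometry as 3D NIfTI files."""
    import nibabel as nib

    if images.geometry is None or images.voxel_ids is None:
        raise ValueError("images lack geometry; NIfTI export needs NIfTI input")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = images.geometry["shape"]
    affine = images.geometry["affine"]
    written = {}
    for name, vec in (("A", images.A_img), ("D", images.D_img), ("S", images.S_img)):
        vol = np.zeros(int(np.prod(shape)))
        vol[images.voxel_ids] = vec
        img = nib.Nifti1Image(vol.reshape(shape, order="F"), affine)
        p = out_dir / f"{prefix}_{name}var.nii"
        nib.save(img, str(p))
        written[name] = p
    return written


def write_null_model_json(null, path, extra: dict | None = None) -> None:
    payload = null.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, config: dict, inputs: list[str]) -> None:
    """Record package version, configuration and input hashes for a run."""
    from . import __version__

    payload = {
        "version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).is_file()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
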