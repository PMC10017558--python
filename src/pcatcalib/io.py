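"""Reading and writing CT volumes and ground-truth masks.

Volumes are stored as NIfTI-1 (.nii.gz), HU as signed 16-bit with
``scl_slope = 1``; acquisition metadata (kVp, reconstruction label) lives
in a sidecar JSON next to each volume, since NIfTI has no kVp field. A
DICOM series directory can be read too (KVP tag (0018,0060), rescale
slope/intercept applied). Only axis-aligned, positive-diagonal affines are
accepted: resampling/registration is out of scope, and index-identity VOI
transfer relies on it.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import CTVolume, GridGeometry


class VolumeIOError(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: CTVolume, path, sidecar: bool = True) -> Path:
    """Write HU data as int16 NIfTI-1 (scl_slope = 1) plus a metadata sidecar."""
    path = Path(path)
    data = np.rint(volume.data).astype(np.int16)
    img = nib.Nifti1Image(data, affine=volume.grid.affine)
    img.header.set_data_dtype(np.int16)
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    nib.save(img, str(path))
    if sidecar:
        meta = {"kvp": volume.kvp, "recon": volume.recon, "volume_id": volume.volume_id}
        meta.update(volume.extra)
        _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_mask(mask: np.ndarray, grid: GridGeometry, path) -> Path:
    """Write a label/boolean mask as a companion NIfTI label volume."""
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine=grid.affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))
    return Path(path)


def read_volume(path, kvp: int | None = None, recon: str | None = None) -> CTVolume:
    """Read a NIfTI volume (or a DICOM series directory) as true HU.

    Scale slope/intercept are applied so returned values are HU. Metadata
    is taken from the sidecar JSON when present; explicit ``kvp``/``recon``
    arguments override it.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, kvp=kvp, recon=recon)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeIOError(f"expected a 3D volume, got shape {img.shape}")
    slope = float(img.dataobj.slope)
    if not np.isfinite(slope) or slope == 0.0:
        raise VolumeIOError(f"ambiguous HU scaling: effective scale slope is {slope}")
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6) or np.any(np.diag(rot) <= 0):
        raise VolumeIOError(
            "only axis-aligned volumes with positive voxel spacing are supported; "
            "resample the image first"
        )
    grid = GridGeometry(
        shape=tuple(int(s) for s in img.shape),
        spacing=tuple(float(d) for d in np.diag(rot)),
        origin=tuple(float(o) for o in affine[:3, 3]),
    )
    data = np.asarray(img.get_fdata(dtype=np.float64))  # slope/inter applied by nibabel

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    vol_kvp = kvp if kvp is not None else meta.get("kvp")
    vol_recon = recon if recon is not None else meta.get("recon")
    extra = {k: v for k, v in meta.items() if k not in {"kvp", "recon", "volume_id"}}
    return CTVolume(
        data=data,
        grid=grid,
        kvp=None if vol_kvp is None else int(vol_kvp),
        recon=vol_recon,
        volume_id=meta.get("volume_id", path.name),
        extra=extra,
    )


def _read_dicom_series(dirpath: Path, kvp: int | None = None, recon: str | None = None) -> CTVolume:
    import pydicom

    files = sorted(p for p in dirpath.iterdir() if p.suffix.lower() in {".dcm", ".ima"})
    if not files:
        files = sorted(p for p in dirpath.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM stragglers in the directory
            continue
    if len(datasets) < 2:
        raise VolumeIOError(f"no DICOM series found in {dirpath}")
    # sort slices along the normal by ImagePositionPatient z
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    z0 = float(datasets[0].ImagePositionPatient[2])
    z1 = float(datasets[1].ImagePositionPatient[2])
    dz = z1 - z0
    if dz <= 0:
        raise VolumeIOError("DICOM slices are not strictly increasing along z")
    rows_spacing, cols_spacing = (float(v) for v in datasets[0].PixelSpacing)
    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        inter = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + inter)
    data = np.stack(slices, axis=-1)  # (row, col, slice)
    origin = (
        float(datasets[0].ImagePositionPatient[0]),
        float(datasets[0].ImagePositionPatient[1]),
        z0,
    )
    grid = GridGeometry(shape=data.shape, spacing=(rows_spacing, cols_spacing, dz), origin=origin)
    tag_kvp = getattr(datasets[0], "KVP", None)
    return CTVolume(
        data=data,
        grid=grid,
        kvp=kvp if kvp is not None else (int(float(tag_kvp)) if tag_kvp is not None else None),
        recon=recon,
        volume_id=dirpath.name,
    )
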