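"""NIfTI input/output and result bundles.

Volumes and label maps round-trip through nibabel with their affine headers
preserved. Displacement and velocity fields are written as 4-D NIfTI with 3
components on the last axis and the vector intent code; vectors are stored
in voxel units (a flag converts to physical mm via the header spacing on
write). ``write_result`` lays a registration result out as a directory with
a checksummed manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import Volume, LabelMap, DisplacementField, VelocityField

__all__ = ["read_volume", "read_labels", "read_field",
           "write_volume", "write_labels", "write_field", "write_result"]


def _load(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nib.load(str(path))


def _spacing(img) -> tuple:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume(path) -> Volume:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D scalar image, got shape {data.shape}")
    return Volume(np.asarray(data, dtype=np.float32), spacing=_spacing(img))


def read_labels(path) -> LabelMap:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D label image, got shape {data.shape}")
    return LabelMap(data)


def read_field(path) -> DisplacementField:
    img = _load(path)
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    data = np.squeeze(data)  # tolerate (D, H, W, 1, 3) vector layout
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"expected a 3-component vector field, got shape {data.shape}")
    return DisplacementField(np.moveaxis(data, -1, 0))


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: Volume, path, affine=None) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, np.float32),
                          affine if affine is not None else _affine(vol.spacing))
    nib.save(img, str(path))


def write_labels(lab: LabelMap, path, affine=None) -> None:
    img = nib.Nifti1Image(lab.data.astype(np.int16),
                          affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def write_field(u, path, affine=None, spacing=(1.0, 1.0, 1.0),
                to_mm: bool = False) -> None:
    """Write a displacement/velocity field as 4-D vector NIfTI.

    ``to_mm=True`` multiplies each component by the voxel spacing so the
    stored vectors are physical millimeters instead of voxel units.
    """
    data = np.moveaxis(np.asarray(u.data, np.float32), 0, -1)
    if to_mm:
        data = data * np.asarray(spacing, np.float32)
    img = nib.Nifti1Image(data, affine if affine is not None else _affine(spacing))
    img.header.set_intent("vector")
    desc = "voxel displacement" if not to_mm else "mm displacement"
    img.header["descrip"] = desc.encode()
    nib.save(img, str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_result(result, outdir, config: dict | None = None,
                 metrics: dict | None = None) -> dict:
    """Write warped volumes, fields, loss trace, metrics and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_volume(result.warped_moving, outdir / "warped_moving.nii.gz")
    write_volume(result.warped_fixed, outdir / "warped_fixed.nii.gz")
    write_field(result.forward_field, outdir / "forward_field.nii.gz")
    write_field(result.inverse_field, outdir / "inverse_field.nii.gz")

    with open(outdir / "loss_trace.csv", "w", newline="") as fh:
        rows = [bd.as_row() for bd in result.loss_trace]
        writer = csv.DictWriter(
            fh, fieldnames=["iteration"] + (list(rows[0]) if rows else []))
        writer.writeheader()
        for i, row in enumerate(rows):
            writer.writerow({"iteration": i, **row})

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics or {}, fh, indent=2)
    if config is not None:
        with open(outdir / "config.json", "w") as fh:
            json.dump(config, fh, indent=2, default=str)

    manifest = {"artifacts": {}}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest["artifacts"][p.name] = {"sha256": _sha256(p),
                                         "bytes": p.stat().st_size}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
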