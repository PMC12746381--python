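"""Serialization: NIfTI volumes, coil JSON, ratio CSV.

Voxel models are written as an int16 NIfTI-1 label volume plus one NIfTI
per mask and a JSON sidecar with the tissue table and grid metadata. The
NIfTI affine is diagonal with the voxel spacing in mm and the origin
converted from meters.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .coils import CoilModel, Loop
from .em_solver import EFieldMap
from .phantoms import TissueTable, VoxelModel


def _affine(model: VoxelModel) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = model.spacing
    aff[:3, 3] = model.origin * 1e3  # m -> mm
    return aff


def save_voxel_model(model: VoxelModel, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(model)
    nib.save(nib.Nifti1Image(model.labels.astype(np.int16), aff), outdir / "labels.nii")
    for name, mask in model.masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), outdir / f"mask_{name}.nii")
    sidecar = {
        "name": model.name,
        "spacing_mm": model.spacing,
        "origin_m": model.origin.tolist(),
        "tissues": [list(e) for e in model.tissues.entries],
        "masks": sorted(model.masks),
    }
    (outdir / "model.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def load_voxel_model(indir: str | Path) -> VoxelModel:
    indir = Path(indir)
    meta = json.loads((indir / "model.json").read_text())
    labels = np.asanyarray(nib.load(indir / "labels.nii").dataobj).astype(np.int16)
    masks = {
        name: np.asanyarray(nib.load(indir / f"mask_{name}.nii").dataobj).astype(bool)
        for name in meta["masks"]
    }
    return VoxelModel(
        labels=labels,
        spacing=float(meta["spacing_mm"]),
        origin=np.array(meta["origin_m"]),
        tissues=TissueTable(entries=tuple((int(l), n, float(s)) for l, n, s in meta["tissues"])),
        masks=masks,
        name=meta.get("name", indir.name),
    )


def save_coil(coil: CoilModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "name": coil.name,
        "axis": coil.axis,
        "inner_diameter_m": coil.inner_diameter,
        "length_m": coil.length,
        "loops": [
            {"vertices": loop.vertices.tolist(), "current": loop.current} for loop in coil.loops
        ],
    }
    path.write_text(json.dumps(doc))
    return path


def load_coil(path: str | Path) -> CoilModel:
    doc = json.loads(Path(path).read_text())
    return CoilModel(
        loops=[Loop(np.array(l["vertices"]), float(l["current"])) for l in doc["loops"]],
        axis=doc["axis"],
        inner_diameter=float(doc["inner_diameter_m"]),
        length=float(doc["length_m"]),
        name=doc.get("name", Path(path).stem),
    )


def save_efield(emap: EFieldMap, model: VoxelModel, path: str | Path) -> Path:
    """Write vectors as a 4-D NIfTI and magnitude as a 3-D NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(model)
    nib.save(nib.Nifti1Image(emap.vectors.astype(np.float32), aff), path)
    mag_path = path.with_name(path.name.replace(".nii", "_mag.nii"))
    nib.save(nib.Nifti1Image(emap.magnitude.astype(np.float32), aff), mag_path)
    return path
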