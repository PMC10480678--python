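"""NIfTI volume and sidecar serialisation.

Volumes (code phantoms, activity maps, attenuation maps, reconstructions)
travel as NIfTI with the voxel spacing in the affine; phantom metadata that
NIfTI cannot hold (height, name, imaged range, per-phantom structure
table) goes in a JSON sidecar plus a CSV table next to the volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import CodePhantom
from .structures import StructureTable


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(path, values: np.ndarray, spacing, sidecar: dict | None = None) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(values), _affine(spacing)), str(path))
    if sidecar is not None:
        path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float], dict]:
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    side = path.with_suffix("").with_suffix(".json")
    sidecar = json.loads(side.read_text()) if side.exists() else {}
    return np.asarray(img.dataobj), spacing, sidecar


def save_phantom(phantom: CodePhantom, stem) -> None:
    """Write <stem>.nii (int codes), <stem>.json (metadata), <stem>_table.csv."""
    stem = Path(stem)
    sidecar = {
        "name": phantom.name,
        "height_m": phantom.height_m,
        "imaged_range": list(phantom.imaged_range),
        "meta": {k: _jsonable(v) for k, v in phantom.meta.items()},
    }
    save_volume(stem.with_suffix(".nii"), phantom.codes.astype(np.int16), phantom.spacing, sidecar)
    if phantom.table is not None:
        phantom.table.to_csv(stem.parent / f"{stem.name}_table.csv")


def load_phantom(stem) -> CodePhantom:
    stem = Path(stem)
    codes, spacing, sidecar = load_volume(stem.with_suffix(".nii"))
    table_path = stem.parent / f"{stem.name}_table.csv"
    table = StructureTable.from_csv(table_path) if table_path.exists() else None
    return CodePhantom(
        codes=np.asarray(codes, dtype=np.int16),
        spacing=spacing,
        height_m=float(sidecar["height_m"]),
        imaged_range=tuple(sidecar["imaged_range"]),
        name=sidecar.get("name", stem.name),
        table=table,
        meta=sidecar.get("meta", {}),
    )


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    return v
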