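"""File-format helpers: NIfTI volumes, b-value sidecars, TIFF slides, JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "save_nifti", "load_nifti", "write_bvals", "read_bvals",
    "write_slide", "read_slide", "write_json", "read_json", "sha256_file",
]


def save_nifti(data, affine, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))
    return path


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_bvals(b_values, path) -> Path:
    """FSL-style single-line .bval text sidecar."""
    path = Path(path)
    path.write_text(" ".join(f"{float(b):g}" for b in b_values) + "\n")
    return path


def read_bvals(path):
    return tuple(float(tok) for tok in Path(path).read_text().split())


def write_slide(rgb, um_per_px: float, path, truth=None) -> Path:
    """RGB TIFF plus a JSON sidecar carrying the scale (and truth if given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(rgb, dtype=np.uint8))
    sidecar = {"um_per_px": float(um_per_px)}
    if truth is not None:
        sidecar["truth"] = {
            "radii_um": [float(r) for r in truth.radii_um],
            "centers_px": [[float(v) for v in c] for c in truth.centers_px],
            "field_area_mm2": float(truth.field_area_mm2),
            "density": float(truth.density),
            "vsi_histo": float(truth.vsi_histo) if truth.count else None,
        }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_slide(path):
    rgb = tifffile.imread(str(path))
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return rgb, sidecar


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
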