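"""NIfTI and sidecar I/O.

Volumes are NIfTI-1.  Gzipped files are written with a fixed gzip
header timestamp (mtime = 0) so that identical data produce identical
bytes, which makes rerun outputs hash-stable.  4-D CEST stacks carry a
TSV sidecar (``offset_ppm``, ``is_reference``) in acquisition order;
contrast maps carry a JSON sidecar recording the analysis parameters.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .schedule import OffsetSchedule
from .zspec import ContrastMap, MapKind, ZSpectrumStack

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_stack",
    "load_stack",
    "save_contrast_map",
    "load_contrast_map",
    "save_mask",
    "load_mask",
    "write_json",
    "sha256_file",
]


def _affine(voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_nifti(data: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0), dtype=np.float32) -> Path:
    """Write a volume as NIfTI-1, gzipping deterministically for .nii.gz."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(voxel_size))
    if path.name.endswith(".nii.gz"):
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))
    return path


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_mask(mask: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    return save_nifti(np.asarray(mask, dtype=np.uint8), path, voxel_size, dtype=np.uint8)


def load_mask(path) -> np.ndarray:
    return load_nifti(path) > 0.5


def save_stack(stack: ZSpectrumStack, stem, voxel_size=(1.0, 1.0, 1.0)) -> list[Path]:
    """Write a CEST stack as <stem>.nii.gz + <stem>_ref.nii.gz + <stem>_offsets.tsv."""
    stem = Path(stem)
    paths = [
        save_nifti(stack.intensities, stem.with_name(stem.name + ".nii.gz"), voxel_size),
        save_nifti(stack.reference_volume, stem.with_name(stem.name + "_ref.nii.gz"), voxel_size),
    ]
    tsv = stem.with_name(stem.name + "_offsets.tsv")
    stack.schedule.to_tsv(tsv)
    return paths + [tsv]


def load_stack(stem) -> ZSpectrumStack:
    stem = Path(stem)
    return ZSpectrumStack(
        intensities=load_nifti(stem.with_name(stem.name + ".nii.gz")),
        schedule=OffsetSchedule.from_tsv(stem.with_name(stem.name + "_offsets.tsv")),
        reference_volume=load_nifti(stem.with_name(stem.name + "_ref.nii.gz")),
    )


def save_contrast_map(cmap: ContrastMap, path, voxel_size=(1.0, 1.0, 1.0)) -> list[Path]:
    """Write map values (NaN off-mask) plus a JSON sidecar with parameters."""
    path = Path(path)
    vals = np.where(cmap.valid_mask, cmap.values, np.nan)
    p1 = save_nifti(vals, path, voxel_size)
    sidecar = path.with_name(path.name.replace(".nii.gz", "").replace(".nii", "") + ".json")
    write_json({"kind": cmap.kind.value, "units": cmap.units, **cmap.meta}, sidecar)
    return [p1, sidecar]


def load_contrast_map(path) -> ContrastMap:
    path = Path(path)
    vals = load_nifti(path)
    sidecar = path.with_name(path.name.replace(".nii.gz", "").replace(".nii", "") + ".json")
    meta = json.loads(sidecar.read_text())
    kind = MapKind(meta.pop("kind"))
    units = meta.pop("units", "percent")
    return ContrastMap(vals, kind, np.isfinite(vals), units=units, meta=meta)


def write_json(obj, path) -> Path:
    """Canonical JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
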