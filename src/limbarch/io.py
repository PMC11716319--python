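"""File I/O: NIfTI volumes, FSL bval/bvec gradient tables, label sidecars.

NIfTI affines are diagonal in the voxel spacing (axis-aligned grids, origin
at the corner), matching the package's world-coordinate convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DWIStack, LabeledMask3D

__all__ = [
    "save_mask",
    "load_mask",
    "save_image",
    "load_image",
    "save_dwi",
    "load_dwi",
    "save_label_map",
    "load_label_map",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def save_image(array: np.ndarray, spacing, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array), _affine(spacing)), str(path))


def load_image(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj), spacing


def save_mask(mask: LabeledMask3D, path, label_path=None) -> None:
    """Write a labeled mask as NIfTI, optionally with a JSON label sidecar."""
    save_image(mask.voxels.astype(np.int16), mask.spacing, path)
    if label_path is not None:
        save_label_map(mask.labels, label_path)


def load_mask(path, label_path=None, labels: dict[int, str] | None = None) -> LabeledMask3D:
    """Read a labeled mask; label names from a sidecar file or explicit dict.

    Without either, labels are named ``label_<id>``.
    """
    vox, spacing = load_image(path)
    vox = np.asarray(vox).astype(np.int32)
    if labels is None:
        if label_path is not None:
            labels = load_label_map(label_path)
        else:
            labels = {int(v): f"label_{int(v)}" for v in np.unique(vox) if v != 0}
    return LabeledMask3D(vox, spacing, labels)


def save_label_map(labels: dict[int, str], path) -> None:
    Path(path).write_text(json.dumps({str(k): v for k, v in labels.items()}, indent=2))


def load_label_map(path) -> dict[int, str]:
    """Read a label sidecar: JSON ``{id: name}`` or ITK-SNAP description text.

    ITK-SNAP label description lines look like::

        1  255 0 0  1 1 1  "medial_gastrocnemius"
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        return {int(k): str(v) for k, v in json.loads(text).items()}
    labels: dict[int, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split('"')
        if len(parts) >= 2:
            lid = int(line.split()[0])
            if lid != 0:
                labels[lid] = parts[1]
    if not labels:
        raise ValueError(f"no labels parsed from {path}")
    return labels


def save_dwi(stack: DWIStack, nifti_path, bval_path, bvec_path) -> None:
    """Write a DWI stack as NIfTI plus FSL-style bval/bvec text files."""
    save_image(stack.signal, stack.spacing, nifti_path)
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in stack.b_values) + "\n")
    lines = [" ".join(f"{v:.10g}" for v in stack.gradients[:, i]) for i in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def load_dwi(nifti_path, bval_path, bvec_path) -> DWIStack:
    signal, spacing = load_image(nifti_path)
    b_values = np.loadtxt(str(bval_path)).ravel()
    bvec = np.loadtxt(str(bvec_path))
    if bvec.shape[0] == 3:
        bvec = bvec.T
    return DWIStack(np.asarray(signal, dtype=float), bvec, b_values, spacing)
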