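"""Shared in-memory containers for labeled volumes and diffusion-weighted stacks.

Conventions used throughout the package:

* arrays are indexed ``[x, y, z]`` with voxel spacing ``(dx, dy, dz)`` in mm;
* axial slices are taken along the last (z) axis;
* world coordinates are axis-aligned with the origin at the grid corner, so a
  voxel with index ``(i, j, k)`` has its center at ``((i+0.5)*dx, (j+0.5)*dy,
  (k+0.5)*dz)`` — all geometry is expressed in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledMask3D", "DWIStack", "TensorField", "voxel_center_coords"]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three strictly positive mm values, got {spacing}")
    return spacing


@dataclass
class LabeledMask3D:
    """Integer label grid with voxel spacing and a label dictionary.

    Parameters
    ----------
    voxels : ndarray of int, shape (nx, ny, nz)
        Per-voxel label ids; 0 is background.
    spacing : (dx, dy, dz)
        Voxel spacing in mm, strictly positive.
    labels : dict
        Maps each nonzero label id occurring in ``voxels`` to a name.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer label grid")
        self.spacing = _check_spacing(self.spacing)
        present = set(np.unique(self.voxels).tolist()) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} appear in the grid but not in the label map")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def id_for(self, label: int | str) -> int:
        """Resolve a label given either its id or its name."""
        if isinstance(label, str):
            for lid, name in self.labels.items():
                if name == label:
                    return lid
            raise KeyError(f"unknown label name {label!r}; known: {sorted(self.labels.values())}")
        if label not in self.labels:
            raise KeyError(f"unknown label id {label}; known ids: {sorted(self.labels)}")
        return int(label)

    def binary(self, label: int | str | None = None) -> np.ndarray:
        """Boolean foreground mask, for one label or for all nonzero voxels."""
        if label is None:
            return self.voxels != 0
        return self.voxels == self.id_for(label)


def voxel_center_coords(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (mm) of voxel centers as a sparse open grid."""
    spacing = _check_spacing(spacing)
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


@dataclass
class DWIStack:
    """A diffusion-weighted image stack with its gradient table.

    ``signal`` is (nx, ny, nz, nvol); ``gradients`` is (nvol, 3) unit vectors
    (the b=0 volume carries a zero row); ``b_values`` is (nvol,) in s/mm^2.
    """

    signal: np.ndarray
    gradients: np.ndarray
    b_values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        nvol = self.signal.shape[3]
        if self.gradients.shape != (nvol, 3):
            raise ValueError(
                f"gradient table shape {self.gradients.shape} does not match {nvol} volumes"
            )
        if self.b_values.shape != (nvol,):
            raise ValueError("one b-value per volume required")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.b_values == 0)


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors (mm^2/s) with a validity mask."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    valid: np.ndarray  # (nx, ny, nz) bool
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if self.valid.shape != self.tensors.shape[:3]:
            raise ValueError("validity mask shape must match the tensor grid")
        self.spacing = _check_spacing(self.spacing)
        # store symmetrized: downstream eigendecompositions assume symmetry
        self.tensors = 0.5 * (self.tensors + np.swapaxes(self.tensors, 3, 4))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending, (..., 3)) and eigenvectors (..., 3, 3).

        ``eigenvectors[..., :, i]`` is the unit eigenvector for eigenvalue i;
        index 0 is the principal (largest) one.
        """
        w, v = np.linalg.eigh(self.tensors)  # ascending
        return w[..., ::-1], v[..., :, ::-1]
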