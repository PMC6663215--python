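"""Anchoring shape graphs into volumetric (brain) anatomy.

Maps between 4-D NIfTI time-series images and the samples x features matrix,
and writes node-wise average activation patterns back into volume space.
Feature columns correspond to the nonzero voxels of a 3-D binary mask in
ascending row-major (C-order) flat-index order; that ordering is the contract
for every function here, so extract -> unmask round-trips exactly.

No detrending or standardization is applied at load; preprocessing (e.g.,
:func:`shapegraph.matrix.normalize_frames`) is the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .mapper import ShapeGraph
from .matrix import DataMatrix

__all__ = [
    "VoxelMask",
    "load_mask",
    "load_masked_timeseries",
    "node_activation_vector",
    "unmask_to_volume",
    "save_activation_nifti",
    "fetch_haxby_masked",
]


@dataclass
class VoxelMask:
    """3-D binary voxel grid plus its voxel-to-world affine.

    ``flat_indices`` lists the C-order flat indices of nonzero voxels; matrix
    column j corresponds to ``flat_indices[j]``.
    """

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if not self.grid.any():
            raise ValueError("mask has no nonzero voxels")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.grid.reshape(-1))


def load_mask(mask_path: str | Path) -> VoxelMask:
    """Load a 3-D NIfTI mask; any nonzero voxel is treated as inside."""
    img = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {data.shape}")
    return VoxelMask(data != 0, img.affine)


def load_masked_timeseries(
    image_path: str | Path, mask_path: str | Path
) -> tuple[DataMatrix, VoxelMask]:
    """Extract a T x V matrix from a 4-D image restricted to a mask.

    V is the number of nonzero mask voxels; column order is ascending C-order
    flat index (see :class:`VoxelMask`).  The image and mask must share grid
    shape and affine.
    """
    img = nib.load(str(image_path))
    mask = load_mask(mask_path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"time-series image must be 4-D, got shape {data.shape}")
    if data.shape[:3] != mask.grid.shape:
        raise ValueError(
            f"image grid {data.shape[:3]} does not match mask grid {mask.grid.shape}"
        )
    if not np.allclose(img.affine, mask.affine, atol=1e-4):
        raise ValueError("image and mask affines differ")
    # data[mask.grid] walks nonzero voxels in C order -> (V, T); transpose
    matrix = np.asarray(data[mask.grid], dtype=float).T
    frames = [f"t{i:04d}" for i in range(matrix.shape[0])]
    voxels = [f"v{j:06d}" for j in mask.flat_indices]
    return DataMatrix(matrix, frames, voxels), mask


def node_activation_vector(
    data: DataMatrix,
    graph: ShapeGraph,
    node_id: int,
    include_neighbors: bool = True,
) -> np.ndarray:
    """Average the data rows of a node's frames (and by default its neighbors').

    Frames appearing in both the node and a neighboring node are counted
    once.  Returns a length-V vector in signal units.
    """
    node = graph.node(node_id)  # raises KeyError for unknown nodes
    frames = set(node.members)
    if include_neighbors:
        for nb in graph.neighbors(node_id):
            frames.update(graph.node(nb).members)
    rows = sorted(frames)
    return data.values[rows].mean(axis=0)


def unmask_to_volume(vector: np.ndarray, mask: VoxelMask) -> np.ndarray:
    """Place a length-V vector back onto the mask's voxel grid (zeros outside)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (mask.n_voxels,):
        raise ValueError(
            f"vector length {vector.shape} does not match mask voxel count {mask.n_voxels}"
        )
    vol = np.zeros(mask.grid.shape, dtype=float)
    vol[mask.grid] = vector  # same C-order walk as extraction
    return vol


def save_activation_nifti(
    volume: np.ndarray, mask: VoxelMask, path: str | Path
) -> None:
    """Write an activation volume as NIfTI-1, preserving the mask's affine."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), mask.affine)
    nib.save(img, str(path))


def fetch_haxby_masked(subject: int = 1, data_dir: str | None = None):
    """Download the Haxby visual-object dataset and extract its VT-mask matrix.

    Optional convenience requiring network access and nilearn; returns
    ``(DataMatrix, VoxelMask)`` for the subject's ventral-temporal mask
    (e.g., 577 voxels for subject 1).  Never used by the test suite.
    """
    from nilearn import datasets  # deferred: optional dependency path

    haxby = datasets.fetch_haxby(subjects=[subject], data_dir=data_dir)
    return load_masked_timeseries(haxby.func[0], haxby.mask_vt[0])
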