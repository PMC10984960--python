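"""Gray-matter volume containers, brain masks, and 3D <-> 1D reshaping.

Source-based morphometry operates on a cohort of spatially normalized,
modulated gray-matter (GM) maps.  Each subject's 3D grid is reduced to the
voxels inside a brain mask and laid out as one row of a subjects x voxels
matrix; all downstream decomposition and regression happens on that matrix.
Flattening uses C order (last axis fastest) and is an exact bijection on the
masked cells, so component maps can be folded back into 3D grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GMVolume",
    "BrainMask",
    "FlatMatrix",
    "flatten_volumes",
    "unflatten",
]

#: Grid of the MNI-space 2 mm isotropic template commonly used for GM maps.
MNI_2MM_SHAPE = (91, 109, 91)

#: Small desk-scale grid used by the synthetic cohort presets.
DESK_GRID_SHAPE = (24, 28, 24)


@dataclass
class GMVolume:
    """One subject's modulated gray-matter map on a regular voxel grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Modulated GM density (unitless).
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    subject_id : str
        Identifier used to align volumes with the subject table.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"GMVolume expects a 3D grid, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite voxels in volume {self.subject_id!r}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


@dataclass
class BrainMask:
    """Boolean inclusion mask on the cohort grid."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 3:
            raise ValueError("BrainMask expects a 3D boolean grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.include.shape)  # type: ignore[return-value]

    @property
    def n_voxels_in(self) -> int:
        return int(self.include.sum())

    @classmethod
    def full(cls, grid_shape: tuple[int, int, int]) -> "BrainMask":
        """All-true mask (every voxel retained)."""
        return cls(np.ones(grid_shape, dtype=bool))

    @classmethod
    def from_mean_image(
        cls, volumes: list[GMVolume], threshold: float = 0.0
    ) -> "BrainMask":
        """Mask of voxels whose cohort-mean intensity exceeds ``threshold``."""
        mean = np.mean([v.values for v in volumes], axis=0)
        return cls(mean > threshold)


@dataclass
class FlatMatrix:
    """Subjects x masked-voxels data matrix with its voxel bookkeeping.

    ``voxel_index`` maps each column to its flat C-order index in the 3D
    grid, which makes :func:`unflatten` an exact inverse on masked cells.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.data.ndim != 2:
            raise ValueError("FlatMatrix.data must be 2D (subjects x voxels)")
        if self.data.shape[1] != self.voxel_index.size:
            raise ValueError("column count does not match voxel_index length")
        if np.unique(self.voxel_index).size != self.voxel_index.size:
            raise ValueError("voxel_index contains duplicates")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer coordinates of each column."""
        return np.column_stack(np.unravel_index(self.voxel_index, self.grid_shape))


def flatten_volumes(volumes: list[GMVolume], mask: BrainMask) -> FlatMatrix:
    """Stack masked voxels of every volume into a subjects x voxels matrix.

    Row ``s`` holds subject ``s``'s masked voxels in C order.  Raises
    ``ValueError`` on a grid-shape mismatch or an empty mask.
    """
    if mask.n_voxels_in == 0:
        raise ValueError("empty brain mask: no voxels selected")
    bad = [v.subject_id or str(i) for i, v in enumerate(volumes)
           if v.grid_shape != mask.grid_shape]
    if bad:
        raise ValueError(
            f"grid shape mismatch with mask {mask.grid_shape}: volumes {bad}"
        )
    flat_mask = mask.include.ravel(order="C")
    voxel_index = np.flatnonzero(flat_mask)
    data = np.empty((len(volumes), voxel_index.size), dtype=float)
    for i, vol in enumerate(volumes):
        data[i] = vol.values.ravel(order="C")[voxel_index]
    return FlatMatrix(
        data=data,
        voxel_index=voxel_index,
        grid_shape=mask.grid_shape,
        subject_ids=[v.subject_id or str(i) for i, v in enumerate(volumes)],
    )


def unflatten(
    row: np.ndarray,
    voxel_index: np.ndarray,
    grid_shape: tuple[int, int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Fold one masked-voxel row back into a 3D grid (``fill`` elsewhere)."""
    row = np.asarray(row, dtype=float)
    if row.size != np.asarray(voxel_index).size:
        raise ValueError("row length does not match voxel_index length")
    out = np.full(int(np.prod(grid_shape)), fill, dtype=float)
    out[voxel_index] = row
    return out.reshape(grid_shape, order="C")
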