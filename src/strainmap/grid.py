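"""Voxel-grid containers shared by every pipeline stage.

All volumes in a pipeline run live on a single common grid (the package
performs no registration); the containers here enforce that assumption by
carrying the grid alongside the data and checking compatibility on every
cross-volume operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarMap",
    "StrainTensorField",
    "ComplexModulusField",
    "TENSOR_COMPONENT_ORDER",
]

#: 4th-dimension component order of symmetric tensor volumes.
TENSOR_COMPONENT_ORDER = ("xx", "xy", "yy", "xz", "yz", "zz")


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice with a voxel-to-world affine.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, all entries >= 1.
    voxel_size : tuple of float
        Edge lengths in mm, all > 0.
    affine : (4, 4) ndarray
        Voxel-index to world-coordinate map; must be invertible.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a triple of positive ints, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be positive, got {vs}")
        aff = self.affine
        if aff is None:
            aff = np.diag([vs[0], vs[1], vs[2], 1.0])
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be invertible")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @classmethod
    def default(cls, shape=(48, 56, 48), voxel_size=(2.0, 2.0, 2.0)) -> "VoxelGrid":
        """Desk-scale analysis grid standing in for a stereotaxic template."""
        return cls(shape=shape, voxel_size=voxel_size, affine=None)

    def matches(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.affine, other.affine)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


def _check_mask(mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match grid shape {shape}")
    return mask


@dataclass
class ScalarMap:
    """A scalar volume defined inside a brain mask.

    ``kind`` labels the quantity (``oss``, ``oss_z``, ``mps``, ``damping``,
    ``storage``, ``afd``, ...) and is carried through I/O for provenance.
    Values outside the mask are undefined and never interpreted.
    """

    grid: VoxelGrid
    values: np.ndarray
    mask: np.ndarray
    kind: str = "scalar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        self.mask = _check_mask(self.mask, self.grid.shape)
        inside = self.values[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            bad = np.argwhere(self.mask & ~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value inside mask at voxel {tuple(bad)}")

    @property
    def in_mask(self) -> np.ndarray:
        """1-D view of the in-mask values."""
        return self.values[self.mask]

    def like(self, values: np.ndarray, kind: str) -> "ScalarMap":
        """New map on the same grid/mask."""
        return ScalarMap(grid=self.grid, values=values, mask=self.mask, kind=kind)

    def check_compatible(self, other: "ScalarMap") -> None:
        if not self.grid.matches(other.grid):
            raise ValueError("scalar maps live on different grids")
        if not np.array_equal(self.mask, other.mask):
            raise ValueError("scalar maps have different masks")


@dataclass
class StrainTensorField:
    """Voxelwise symmetric strain tensors (dimensionless Green-Lagrange strain).

    ``components`` is a 4-D array with the six independent entries stored in
    lower-triangular order ``xx, xy, yy, xz, yz, zz`` along the last axis.
    """

    grid: VoxelGrid
    components: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        expected = self.grid.shape + (6,)
        if self.components.shape != expected:
            raise ValueError(
                f"tensor components must have shape {expected}, "
                f"got {self.components.shape} (component order {TENSOR_COMPONENT_ORDER})"
            )
        self.mask = _check_mask(self.mask, self.grid.shape)
        inside = self.components[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            bad_vox = np.argwhere(self.mask & ~np.isfinite(self.components).all(axis=-1))[0]
            raise ValueError(f"non-finite tensor components inside mask at voxel {tuple(bad_vox)}")

    def as_matrices(self) -> np.ndarray:
        """In-mask tensors as an (n, 3, 3) stack of symmetric matrices."""
        c = self.components[self.mask]
        m = np.empty((c.shape[0], 3, 3))
        xx, xy, yy, xz, yz, zz = (c[:, i] for i in range(6))
        m[:, 0, 0] = xx
        m[:, 1, 1] = yy
        m[:, 2, 2] = zz
        m[:, 0, 1] = m[:, 1, 0] = xy
        m[:, 0, 2] = m[:, 2, 0] = xz
        m[:, 1, 2] = m[:, 2, 1] = yz
        return m

    @classmethod
    def from_matrices(
        cls, grid: VoxelGrid, matrices: np.ndarray, mask: np.ndarray
    ) -> "StrainTensorField":
        """Build a field from an (n, 3, 3) stack of in-mask tensors."""
        mask = _check_mask(mask, grid.shape)
        comp = np.zeros(grid.shape + (6,))
        m = np.asarray(matrices, dtype=float)
        if m.shape != (int(mask.sum()), 3, 3):
            raise ValueError("matrices must be (n_mask_voxels, 3, 3)")
        comp[mask, 0] = m[:, 0, 0]
        comp[mask, 1] = m[:, 0, 1]
        comp[mask, 2] = m[:, 1, 1]
        comp[mask, 3] = m[:, 0, 2]
        comp[mask, 4] = m[:, 1, 2]
        comp[mask, 5] = m[:, 2, 2]
        return cls(grid=grid, components=comp, mask=mask)


@dataclass
class ComplexModulusField:
    """Storage (G', Pa) and loss (G'', Pa) modulus volumes from MRE inversion."""

    grid: VoxelGrid
    storage: np.ndarray
    loss: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.storage = np.asarray(self.storage, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        for name, arr in (("storage", self.storage), ("loss", self.loss)):
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {self.grid.shape}")
        self.mask = _check_mask(self.mask, self.grid.shape)
        if np.any(self.storage[self.mask] <= 0):
            raise ValueError("storage modulus G' must be > 0 inside mask")
        if np.any(self.loss[self.mask] < 0):
            raise ValueError("loss modulus G'' must be >= 0 inside mask")
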