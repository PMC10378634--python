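"""Voxel-grid geometry.

Frame convention (fixed throughout the package): x = left-right,
y = anterior-posterior, z = superior-inferior.  All lengths are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """A regular voxel grid: shape in voxels, spacing and origin in mm.

    ``origin`` is the position of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValidationError("GridSpec fields must be length-3")
        if any(s < 1 for s in shape):
            raise ValidationError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValidationError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def centered(cls, shape, spacing) -> "GridSpec":
        """Grid whose voxel-center bounding box is centered on the origin."""
        shape = tuple(int(s) for s in shape)
        spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
        origin = tuple(-sp * (n - 1) / 2.0 for n, sp in zip(shape, spacing))
        return cls(shape, spacing, origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal; axis-aligned grid)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of all voxel-center positions, C-order flattening."""
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def same_geometry(self, other: "GridSpec", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )
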