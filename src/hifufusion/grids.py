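"""Cartesian voxel grids shared by the acoustic and thermal solvers.

Convention (right-handed): x = cranial-caudal, y = transverse,
z = depth along the beam axis, origin at the transducer apex.
Coordinates are voxel centers, in millimeters, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """A regular 3D grid of voxel centers.

    Parameters
    ----------
    origin : tuple of float
        Coordinates (mm) of the center of voxel (0, 0, 0).
    spacing : tuple of float
        Voxel pitch (mm) along (x, y, z); all entries must be positive.
    shape : tuple of int
        Number of voxels along (x, y, z).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError("grid shape must be at least 1 along each axis")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @classmethod
    def from_bounds(
        cls,
        bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
        spacing: float | tuple[float, float, float],
    ) -> "Grid":
        """Build a grid of voxel centers covering ``bounds`` at ``spacing``.

        ``bounds`` are (lo, hi) per axis in mm; the first voxel center sits at
        ``lo`` and the number of voxels is chosen so the last center does not
        exceed ``hi`` by more than half a voxel.
        """
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3  # type: ignore[assignment]
        origin = tuple(float(b[0]) for b in bounds)
        shape = tuple(
            int(np.floor((b[1] - b[0]) / s + 0.5)) + 1
            for b, s in zip(bounds, spacing)  # type: ignore[arg-type]
        )
        return cls(origin, spacing, shape)  # type: ignore[arg-type]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis (0=x, 1=y, 2=z)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def x(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z(self) -> np.ndarray:
        return self.axis_coords(2)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        """(lo, hi) of voxel centers per axis, in mm."""
        return tuple(
            (self.origin[i], self.origin[i] + self.spacing[i] * (self.shape[i] - 1))
            for i in range(3)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense coordinate arrays of shape ``self.shape`` (indexing='ij')."""
        return np.meshgrid(self.x, self.y, self.z, indexing="ij")

    def same_geometry(self, other: "Grid") -> bool:
        return (
            np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
            and self.shape == other.shape
        )
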