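"""Shared voxel-grid containers.

All volumes in this package live on a common regular grid with index order
``(x, y, z)`` and world coordinates (mm) given by

    world = origin + index * spacing

Spacing is anisotropic in general (thoracic CT protocols typically have
sub-millimetre in-plane pixels and multi-millimetre slices), so every
physical computation (gradients, distances, margins, volumes) must go
through the grid geometry rather than raw index arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["GridGeometry", "ImageGrid", "DisplacementField", "StructureMask"]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin shared by all volumes of one patient."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse) world-coordinate arrays X, Y, Z."""
        cx, cy, cz = self.axis_coords()
        return np.meshgrid(cx, cy, cz, indexing="ij", sparse=True)

    def dense_points(self) -> np.ndarray:
        """(N, 3) array of all voxel-center world coordinates."""
        X, Y, Z = np.meshgrid(*self.axis_coords(), indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def close_to(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _check_geometry(data: np.ndarray, geometry: GridGeometry, ncomp: int | None) -> None:
    expect = geometry.shape if ncomp is None else (*geometry.shape, ncomp)
    if data.shape != expect:
        raise ValueError(f"data shape {data.shape} does not match geometry {expect}")


@dataclass
class ImageGrid:
    """A scalar 3D volume (CT intensity in HU, or dose in Gy) on a grid."""

    data: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_geometry(self.data, self.geometry, None)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.geometry.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) in mm, mapping exhale (fixed) coordinates
    to inhale (moving) coordinates: a point at world position ``p`` in the
    exhale frame moves to ``p + u(p)`` in the inhale frame.

    Stored as an ``(nx, ny, nz, 3)`` array with components (u_x, u_y, u_z).
    """

    u: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        _check_geometry(self.u, self.geometry, 3)
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=-1)

    def components(self) -> Iterator[np.ndarray]:
        for c in range(3):
            yield self.u[..., c]


@dataclass
class StructureMask:
    """Binary structure mask (lung, target volume, organ at risk) on a grid."""

    voxels: np.ndarray
    geometry: GridGeometry
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"mask '{self.label}' is not binary (values {uniq[:8]}...)"
            )
        self.voxels = arr.astype(bool)
        _check_geometry(self.voxels, self.geometry, None)

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not self.voxels.any()
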