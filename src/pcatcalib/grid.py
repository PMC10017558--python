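"""Voxel-grid geometry and the in-memory CT volume container.

All physical coordinates are millimetres. A :class:`GridGeometry` maps
0-based voxel indices to the physical positions of voxel *centers* via an
axis-aligned affine (``mm = origin + index * spacing``), the same convention
NIfTI uses for a diagonal s/q-form. Volumes produced at different tube
voltages from one phantom share a grid exactly, which is what makes
index-identity VOI transfer valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Absolute tolerance (mm) below which two grids count as identical.
#: Anything larger is a registration problem, out of scope here.
GRID_TOL_MM = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned voxel grid: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 diagonal affine mapping voxel index to mm (voxel-center)."""
        a = np.eye(4)
        a[[0, 1, 2], [0, 1, 2]] = self.spacing
        a[:3, 3] = self.origin
        return a

    def index_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical positions (mm) of voxel centers for an (N, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each (N, 3) physical point."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return np.rint((pts - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)

    def contains_index(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices))
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)

    def contains_point(self, points_mm: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        """True where a physical point lies inside the grid's voxel-center extent."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        lo = np.asarray(self.origin) - margin_mm
        hi = np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) + margin_mm
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def approx_equal(self, other: "GridGeometry", tol_mm: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense voxel-center coordinate arrays (x_mm, y_mm, z_mm), each of ``shape``."""
        axes = [
            self.origin[k] + np.arange(self.shape[k]) * self.spacing[k]
            for k in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units with acquisition metadata.

    ``kvp`` is the tube voltage the volume was (synthetically) acquired at,
    ``recon`` the reconstruction regime label (``"FBP"`` or ``"IR"``).
    """

    data: np.ndarray
    grid: GridGeometry
    kvp: int | None = None
    recon: str | None = None
    volume_id: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume data must be 3D, got ndim={self.data.ndim}")
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape
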