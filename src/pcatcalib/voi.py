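"""Perivascular tube VOI construction and lumen geometry.

The perivascular region of a vessel is the tissue within a radial distance
of the artery equal to the vessel diameter, forming a tube-like 3D volume
of interest along the traced centerline. Here the tube is realised as a
capsule shell around the centerline polyline: with vessel radius
``r = diameter / 2``, a voxel belongs to the VOI when its center's minimum
distance ``d`` to the centerline satisfies ``r < d <= r + diameter``; the
voxels at ``d <= r`` (the vessel itself) and the segmented lumen are
excluded. Membership is by voxel-center position with no partial-volume
weighting, which keeps an exact brute-force oracle possible.

The measured convention — inner boundary at the vessel radius from the
*centerline* (not from the lumen surface) — is configurable via
``inner_offset_mm`` for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .centerline import Centerline
from .geom import min_polyline_distance
from .grid import GRID_TOL_MM, CTVolume, GridGeometry


class VOIError(ValueError):
    """Raised when a VOI cannot be constructed or transferred."""


class LumenSegmentationError(VOIError):
    """No contrast-filled lumen found near the centerline (failed filling)."""


@dataclass
class TubeVOI:
    """Voxel-index representation of the perivascular tube on a reference grid."""

    reference_grid: GridGeometry
    voxel_indices: np.ndarray  # (N, 3) int, lexicographically sorted
    lumen_indices: np.ndarray  # (M, 3) int, the excluded vessel/lumen voxels
    vessel_diameter_mm: float
    vessel_id: str = "vessel"

    def __post_init__(self) -> None:
        self.voxel_indices = _canonical_indices(self.voxel_indices)
        self.lumen_indices = _canonical_indices(self.lumen_indices)
        if self.voxel_indices.shape[0] == 0:
            raise VOIError("tube VOI is empty")
        for name, idx in (("voxel", self.voxel_indices), ("lumen", self.lumen_indices)):
            if idx.shape[0] and not bool(np.all(self.reference_grid.contains_index(idx))):
                raise VOIError(f"{name}_indices fall outside the reference grid")
        if self.voxel_indices.shape[0] and self.lumen_indices.shape[0]:
            both = set(map(tuple, self.voxel_indices)) & set(map(tuple, self.lumen_indices))
            if both:
                raise VOIError("voxel_indices and lumen_indices overlap")

    @property
    def size_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    def as_set(self) -> set[tuple[int, int, int]]:
        return set(map(tuple, self.voxel_indices))

    def to_mask(self, include_lumen: bool = False) -> np.ndarray:
        """Dense label mask on the reference grid (1 = tube, 2 = excluded lumen)."""
        mask = np.zeros(self.reference_grid.shape, dtype=np.uint8)
        mask[tuple(self.voxel_indices.T)] = 1
        if include_lumen and self.lumen_indices.shape[0]:
            mask[tuple(self.lumen_indices.T)] = 2
        return mask


def _canonical_indices(indices: np.ndarray) -> np.ndarray:
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        return idx.reshape(0, 3)
    idx = np.atleast_2d(idx)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    return idx[order]


def segment_lumen(
    volume: CTVolume,
    centerline: Centerline,
    lumen_threshold_hu: float = 200.0,
    search_radius_mm: float = 5.0,
) -> np.ndarray:
    """Contrast-lumen mask: the bright connected component hit by the centerline.

    Thresholds the volume at ``lumen_threshold_hu``, restricts to a generous
    cylinder around the centerline, and keeps the connected component
    (face connectivity) that intersects the traced points. Raises
    :class:`LumenSegmentationError` when no voxel qualifies — the synthetic
    analogue of a vessel whose contrast filling failed.
    """
    grid = volume.grid
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    lo_mm = centerline.points.min(axis=0) - search_radius_mm - spacing
    hi_mm = centerline.points.max(axis=0) + search_radius_mm + spacing
    lo = np.maximum(np.floor((lo_mm - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((hi_mm - origin) / spacing).astype(int) + 1, np.asarray(grid.shape))
    axes = [origin[k] + np.arange(lo[k], hi[k]) * spacing[k] for k in range(3)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    near = np.zeros(grid.shape, dtype=bool)
    near[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (
        min_polyline_distance(pts, centerline.points) <= search_radius_mm
    ).reshape(xs.shape)
    bright = (volume.data >= lumen_threshold_hu) & near
    if not bright.any():
        raise LumenSegmentationError(
            f"no voxel >= {lumen_threshold_hu} HU within {search_radius_mm} mm of the "
            f"centerline of {centerline.vessel_id!r}: lack of lumen contrast"
        )
    comp, _ = ndimage.label(bright)
    cl_idx = grid.mm_to_index(centerline.points)
    inside = grid.contains_index(cl_idx)
    hit_labels = np.unique(comp[tuple(cl_idx[inside].T)])
    hit_labels = hit_labels[hit_labels > 0]
    if hit_labels.size == 0:
        raise LumenSegmentationError(
            f"no bright component intersects the centerline of {centerline.vessel_id!r}"
        )
    return np.isin(comp, hit_labels)


def estimate_diameter(
    lumen_mask: np.ndarray,
    centerline: Centerline,
    grid: GridGeometry,
    n_stations: int = 12,
    plane_halfwidth_mm: float = 6.0,
    sample_step_mm: float | None = None,
) -> float:
    """Median area-equivalent lumen diameter (mm) across centerline stations.

    At each of ``n_stations`` equally spaced arc-length stations the mask is
    sampled (trilinear) on a fine 2D grid in the plane normal to the local
    tangent; the cross-section area is the >=0.5 iso-region and the station
    diameter is ``2 * sqrt(area / pi)``. The median over stations is robust
    to end effects and to a tapering vessel.
    """
    lumen_mask = np.asarray(lumen_mask)
    if lumen_mask.shape != grid.shape:
        raise VOIError("lumen mask shape does not match grid")
    if not lumen_mask.any():
        raise VOIError("empty lumen mask")
    n_stations = max(int(n_stations), 10)
    if sample_step_mm is None:
        sample_step_mm = 0.25 * min(grid.spacing)
    stations = np.linspace(0.0, centerline.total_length_mm, n_stations + 2)[1:-1]
    u_axis = np.arange(-plane_halfwidth_mm, plane_halfwidth_mm + 1e-9, sample_step_mm)
    uu, vv = np.meshgrid(u_axis, u_axis, indexing="ij")
    field = lumen_mask.astype(np.float32)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)

    diameters = []
    for s in stations:
        p = centerline.point_at(s)[0]
        t = centerline.tangent_at(s)[0]
        # in-plane orthonormal basis
        ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        pts = p + uu[..., None] * u + vv[..., None] * v
        coords = ((pts - origin) / spacing).reshape(-1, 3).T
        vals = ndimage.map_coordinates(field, coords, order=1, mode="constant", cval=0.0)
        area = float((vals >= 0.5).sum()) * sample_step_mm**2
        if area > 0:
            diameters.append(2.0 * np.sqrt(area / np.pi))
    if len(diameters) < 3:
        raise VOIError(
            f"only {len(diameters)} centerline stations have a nonempty lumen "
            "cross-section (need >= 3); mask too degenerate for diameter estimation"
        )
    return float(np.median(diameters))


def build_tube_voi(
    centerline: Centerline,
    diameter_mm: float,
    lumen_mask: np.ndarray | None,
    grid: GridGeometry,
    vessel_id: str | None = None,
    inner_offset_mm: float | None = None,
) -> TubeVOI:
    """Build the perivascular tube VOI around a centerline.

    A voxel center at minimum distance ``d`` from the centerline polyline is
    in the tube when ``inner < d <= inner + diameter_mm`` (half-open shell),
    where ``inner`` defaults to the vessel radius ``diameter_mm / 2``.
    Voxels at ``d <= inner`` and voxels of ``lumen_mask`` are excluded and
    recorded as ``lumen_indices``.
    """
    if diameter_mm <= 0:
        raise VOIError("vessel diameter must be > 0")
    inner = diameter_mm / 2.0 if inner_offset_mm is None else float(inner_offset_mm)
    outer = inner + diameter_mm

    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    lo_mm = centerline.points.min(axis=0) - outer - spacing
    hi_mm = centerline.points.max(axis=0) + outer + spacing
    lo = np.maximum(np.floor((lo_mm - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((hi_mm - origin) / spacing).astype(int) + 1, np.asarray(grid.shape))
    if np.any(lo >= hi):
        raise VOIError("centerline lies outside the grid")

    axes = [origin[k] + np.arange(lo[k], hi[k]) * spacing[k] for k in range(3)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    idx_axes = [np.arange(lo[k], hi[k]) for k in range(3)]
    ii, jj, kk = np.meshgrid(*idx_axes, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])

    d = min_polyline_distance(pts, centerline.points)
    in_shell = (d > inner) & (d <= outer)
    in_vessel = d <= inner
    if lumen_mask is not None:
        lumen_mask = np.asarray(lumen_mask, dtype=bool)
        if lumen_mask.shape != grid.shape:
            raise VOIError("lumen mask shape does not match grid")
        in_lumen = lumen_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        in_lumen = np.zeros(idx.shape[0], dtype=bool)

    tube = in_shell & ~in_lumen
    excluded = in_vessel | (in_lumen & (d <= outer))
    if not tube.any():
        raise VOIError("tube VOI is empty on this grid")
    return TubeVOI(
        reference_grid=grid,
        voxel_indices=idx[tube],
        lumen_indices=idx[excluded],
        vessel_diameter_mm=float(diameter_mm),
        vessel_id=vessel_id or centerline.vessel_id,
    )


def transfer_voi(voi: TubeVOI, target: CTVolume) -> TubeVOI:
    """Rebind a VOI to a co-registered volume (identity transfer).

    The target grid must match the reference grid exactly (shape) and to
    within 1e-6 mm (spacing, origin); anything else needs resampling or
    registration first, which is out of scope.
    """
    if not voi.reference_grid.approx_equal(target.grid, tol_mm=GRID_TOL_MM):
        raise VOIError(
            "target grid does not match the VOI's reference grid "
            f"(reference {voi.reference_grid}, target {target.grid}); "
            "resample/register the volume before transferring the VOI"
        )
    return TubeVOI(
        reference_grid=target.grid,
        voxel_indices=voi.voxel_indices.copy(),
        lumen_indices=voi.lumen_indices.copy(),
        vessel_diameter_mm=voi.vessel_diameter_mm,
        vessel_id=voi.vessel_id,
    )
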