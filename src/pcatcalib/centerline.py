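"""Vessel centerlines: ordered 3D point lists in physical mm.

A centerline traces a coronary artery from its origin; measurements use at
most the first 40 mm (or the full length when shorter), so
:func:`truncate_centerline` cuts exactly at the cap, interpolating the
final point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Default maximum traced length (mm) from the vessel origin.
DEFAULT_MAX_LENGTH_MM = 40.0


@dataclass
class Centerline:
    points: np.ndarray  # (N, 3) mm, ordered from the vessel origin
    vessel_id: str = "vessel"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be an (N, 3) array in mm")
        if self.points.shape[0] < 2:
            raise ValueError("a centerline needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive centerline points must be distinct")

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length (mm) at each point; starts at 0, strictly increasing."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def total_length_mm(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of position at arc length ``s`` (mm)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        arc = self.arc_length
        out = np.empty((s.size, 3))
        for k in range(3):
            out[:, k] = np.interp(s, arc, self.points[:, k])
        return out

    def tangent_at(self, s: float | np.ndarray, h_mm: float = 0.5) -> np.ndarray:
        """Unit tangent at arc length ``s`` by central differences."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        lo = np.clip(s - h_mm, 0.0, self.total_length_mm)
        hi = np.clip(s + h_mm, 0.0, self.total_length_mm)
        t = self.point_at(hi) - self.point_at(lo)
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return t / norms


def truncate_centerline(
    centerline: Centerline, max_length_mm: float = DEFAULT_MAX_LENGTH_MM
) -> Centerline:
    """Cut a centerline at ``max_length_mm`` from its origin, exactly.

    If the trace is shorter than the cap it is returned unchanged. When the
    cap falls inside a segment, the final point is interpolated so the
    returned arc length equals the cap to machine precision.
    """
    if max_length_mm <= 0:
        raise ValueError("max_length_mm must be > 0")
    arc = centerline.arc_length
    if centerline.total_length_mm <= max_length_mm:
        return centerline
    keep = arc < max_length_mm
    last = centerline.point_at(max_length_mm)
    pts = np.vstack([centerline.points[keep], last])
    return Centerline(points=pts, vessel_id=centerline.vessel_id)


# ---------------------------------------------------------------------------
# IO: CSV (vessel_id, x_mm, y_mm, z_mm; row order is point order) and JSON
# ---------------------------------------------------------------------------

def write_centerlines_csv(centerlines: list[Centerline], path) -> None:
    rows = []
    for cl in centerlines:
        for p in cl.points:
            rows.append({"vessel_id": cl.vessel_id, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_centerlines_csv(path) -> list[Centerline]:
    df = pd.read_csv(path)
    required = {"vessel_id", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"centerline CSV must have columns {sorted(required)}")
    out = []
    for vid, grp in df.groupby("vessel_id", sort=False):
        out.append(Centerline(points=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(), vessel_id=str(vid)))
    return out


def write_centerlines_json(centerlines: list[Centerline], path) -> None:
    payload = [
        {"vessel_id": cl.vessel_id, "points_mm": cl.points.tolist()} for cl in centerlines
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_centerlines_json(path) -> list[Centerline]:
    payload = json.loads(Path(path).read_text())
    return [Centerline(points=np.asarray(d["points_mm"]), vessel_id=d["vessel_id"]) for d in payload]
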