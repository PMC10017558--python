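"""Point-to-polyline distance primitives shared by the phantom and VOI code.

The perivascular tube is a capsule union: the distance from a voxel center
to the vessel is the minimum Euclidean distance to any centerline segment.
"""

from __future__ import annotations

import numpy as np


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point in (N, 3) ``points`` to segment ``a``–``b``."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def min_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Minimum distance from each point to an ordered polyline (mm).

    Vectorised over points, looping over segments; for a single-point
    "polyline" this degenerates to plain point distance.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.atleast_2d(np.asarray(polyline, dtype=float))
    if poly.shape[0] == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    d = np.full(points.shape[0], np.inf)
    for i in range(poly.shape[0] - 1):
        np.minimum(d, point_segment_distance(points, poly[i], poly[i + 1]), out=d)
    return d
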