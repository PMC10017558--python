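"""Independent brute-force oracles, deliberately written as per-voxel scalar
loops so they share no code path with the vectorised implementation."""

import math

import numpy as np


def dist_point_segment(p, a, b):
    """Scalar point-to-segment distance."""
    ab = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
    ap = (p[0] - a[0], p[1] - a[1], p[2] - a[2])
    denom = ab[0] ** 2 + ab[1] ** 2 + ab[2] ** 2
    if denom == 0.0:
        return math.dist(p, a)
    t = (ap[0] * ab[0] + ap[1] * ab[1] + ap[2] * ab[2]) / denom
    t = min(max(t, 0.0), 1.0)
    c = (a[0] + t * ab[0], a[1] + t * ab[1], a[2] + t * ab[2])
    return math.dist(p, c)


def dist_point_polyline(p, polyline):
    if len(polyline) == 1:
        return math.dist(p, tuple(polyline[0]))
    return min(
        dist_point_segment(p, tuple(polyline[i]), tuple(polyline[i + 1]))
        for i in range(len(polyline) - 1)
    )


def brute_tube_voi(polyline, diameter, grid, lumen_mask=None):
    """Per-voxel tube membership: radius < d <= radius + diameter, minus lumen.

    Returns (tube_set, excluded_set) of index tuples, matching the
    half-open shell convention with the inner bound at the vessel radius.
    """
    radius = diameter / 2.0
    outer = radius + diameter
    tube, excluded = set(), set()
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                p = (
                    grid.origin[0] + i * grid.spacing[0],
                    grid.origin[1] + j * grid.spacing[1],
                    grid.origin[2] + k * grid.spacing[2],
                )
                d = dist_point_polyline(p, polyline)
                in_lumen = bool(lumen_mask[i, j, k]) if lumen_mask is not None else False
                if radius < d <= outer and not in_lumen:
                    tube.add((i, j, k))
                elif d <= radius or (in_lumen and d <= outer):
                    excluded.add((i, j, k))
    return tube, excluded


def brute_rm_anova_F(x):
    """Textbook within-subjects SS decomposition, scalar loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    subj = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    lev = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_treat = n * sum((m - grand) ** 2 for m in lev)
    ss_subj = k * sum((m - grand) ** 2 for m in subj)
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_treat - ss_subj
    ms_treat = ss_treat / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_treat / ms_err


def brute_cylinder_count(center_xy, radius, grid):
    """Count voxel centers within ``radius`` of a z-axis line (all slices)."""
    count = 0
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            x = grid.origin[0] + i * grid.spacing[0]
            y = grid.origin[1] + j * grid.spacing[1]
            if math.hypot(x - center_xy[0], y - center_xy[1]) <= radius:
                count += 1
    return count * grid.shape[2]
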