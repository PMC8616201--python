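"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: segment distance is
estimated by refined grid sampling, and the analytic point-kernel fluences
are integrated over voxel volumes by sub-sampling rather than evaluated at
voxel centers.
"""

import itertools

import numpy as np


def sampled_segment_distance(a0, a1, b0, b1, n0=256, levels=9, shrink=4.0):
    """Minimum distance between two segments by iteratively refined sampling.

    Evaluates all point pairs on an ``n0 x n0`` parameter grid, then re-grids
    around the best (s, t) with a window shrinking by ``shrink`` per level.
    Independent of the closed-form clamped solution.
    """
    a0, a1, b0, b1 = (np.asarray(p, dtype=float) for p in (a0, a1, b0, b1))
    lo_s, hi_s, lo_t, hi_t = 0.0, 1.0, 0.0, 1.0
    best = np.inf
    for _ in range(levels):
        s = np.linspace(lo_s, hi_s, n0)
        t = np.linspace(lo_t, hi_t, n0)
        pa = a0[None, :] + s[:, None] * (a1 - a0)[None, :]
        pb = b0[None, :] + t[:, None] * (b1 - b0)[None, :]
        d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
        k = np.unravel_index(np.argmin(d2), d2.shape)
        best = min(best, float(np.sqrt(d2[k])))
        ws = (hi_s - lo_s) / shrink
        wt = (hi_t - lo_t) / shrink
        lo_s, hi_s = max(0.0, s[k[0]] - ws), min(1.0, s[k[0]] + ws)
        lo_t, hi_t = max(0.0, t[k[1]] - wt), min(1.0, t[k[1]] + wt)
    return best


def _voxel_subpoints(k):
    offs = (np.arange(k) + 0.5) / k - 0.5
    return np.array(list(itertools.product(offs, offs, offs)))


def voxel_averaged_point_kernel(voxel_centers, source, func, k=16):
    """Average an analytic radial kernel ``func(r)`` over unit voxels.

    ``voxel_centers`` are world coordinates (mm) of 1 mm voxels; ``source``
    is the point-source location.  Sub-samples each voxel on a k^3 grid.
    """
    sub = _voxel_subpoints(k)
    centers = np.asarray(voxel_centers, dtype=float)
    pts = centers[:, None, :] + sub[None, :, :]
    r = np.linalg.norm(pts - np.asarray(source)[None, None, :], axis=2)
    return func(r).mean(axis=1)


def radial_shells(grid_shape, center, voxel_size=1.0):
    """(voxel center coordinates, radius) arrays for shell averaging."""
    idx = np.indices(grid_shape).reshape(3, -1).T * voxel_size
    r = np.linalg.norm(idx - np.asarray(center), axis=1)
    return idx, r


def shell_mean(values_flat, r, r_lo, r_hi):
    sel = (r >= r_lo) & (r < r_hi)
    return float(np.asarray(values_flat)[sel].mean()), sel
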