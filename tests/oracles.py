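"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different routes than the
package (exhaustive per-voxel loops, explicit density integration, surface
triangulation) so agreement is evidence rather than tautology.
"""

import math

import numpy as np
from scipy.integrate import quad


def resample_mask_bruteforce(seg_occ, seg_vox, seg_times, seg_rr, t_shape, t_vox, t_times, t_rr):
    """Voxel-by-voxel nearest-neighbour resampling (spatial + normalized
    cycle time), exhaustive loops."""
    n_t = len(t_times)
    out = np.zeros((n_t,) + tuple(t_shape), dtype=bool)
    s_norm = np.asarray(seg_times) / seg_rr
    for t in range(n_t):
        sf = int(np.argmin(np.abs(t_times[t] / t_rr - s_norm)))
        for i in range(t_shape[0]):
            for j in range(t_shape[1]):
                for k in range(t_shape[2]):
                    src = []
                    ok = True
                    for ax, idx in enumerate((i, j, k)):
                        s = int(round(idx * t_vox[ax] / seg_vox[ax]))
                        if s < 0 or s >= seg_occ.shape[1 + ax]:
                            ok = False
                            break
                        src.append(s)
                    if ok:
                        out[t, i, j, k] = seg_occ[sf, src[0], src[1], src[2]]
    return out


def t_sf_numeric(t_value, df):
    """Upper-tail probability of the t distribution by direct quadrature of
    the explicit density (log-gamma normalization; no scipy.stats)."""
    logc = (
        math.lgamma((df + 1) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )

    def pdf(x):
        return math.exp(logc - (df + 1) / 2.0 * math.log1p(x * x / df))

    val, _ = quad(pdf, abs(t_value), np.inf, limit=200)
    return val


def t_pvalue_numeric(t_value, df):
    """Two-sided p-value by numeric integration."""
    return 2.0 * t_sf_numeric(t_value, df)


def surface_integral_pressure(alpha, radius_mm, grid, voxel_mm):
    """Brute-force surface integral of p = alpha * x over a triangulated
    sphere: sum over marching-cubes triangles of p(centroid) * area * n_hat.

    Returns the 3-vector surface force (units of alpha * mm^3; the caller
    scales to SI).
    """
    from skimage.measure import marching_cubes

    ax = (np.arange(grid) - (grid - 1) / 2.0) * voxel_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    level = radius_mm**2 - (X**2 + Y**2 + Z**2)  # positive inside
    verts, faces, _, _ = marching_cubes(level, 0.0, spacing=(voxel_mm,) * 3)
    verts = verts - (grid - 1) * voxel_mm / 2.0  # center coordinates
    tri = verts[faces]
    centroids = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    # orient normals outward (away from the sphere center)
    sign = np.sign(np.einsum("ij,ij->i", cross, centroids))
    cross *= sign[:, None]
    p = alpha * centroids[:, 0]
    return 0.5 * (cross * p[:, None]).sum(axis=0)


def unwrap_series_bruteforce(series, venc, max_wraps=2):
    """Exhaustive search over wrap integers minimizing cyclic total variation
    (anchored at the minimal-|v| frame)."""
    from itertools import product

    s = np.asarray(series, dtype=float)
    n = len(s)
    ref = int(np.argmin(np.abs(s)))
    order = [(ref + i) % n for i in range(n)]
    best, best_tv = None, np.inf
    for assign in product(range(-max_wraps, max_wraps + 1), repeat=n - 1):
        cand = s.copy()
        for frame, k in zip(order[1:], assign):
            cand[frame] += 2.0 * venc * k
        tv = np.abs(np.diff(cand[order + [ref]])).sum()
        if tv < best_tv - 1e-12:
            best_tv, best = tv, cand
    return best
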