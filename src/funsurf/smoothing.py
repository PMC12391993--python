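"""Binned local-linear kernel smoothers for sparse functional data.

Raw pooled observations (for the mean) and raw pairwise cross-products (for
the covariance surface) are first accumulated onto the analysis grid; the
local-linear fits then run on the binned sums with bin counts as weights.
This keeps the cost independent of the number of subjects while matching the
usual bias behaviour of local-linear smoothing (design bias only through the
bin width, which is small relative to the bandwidth).
"""

from __future__ import annotations

import numpy as np

_RIDGE = 1e-10


def bin_points_1d(x, y, grid):
    """Accumulate (x, y) onto nearest grid points; returns (sums, counts)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    idx = np.clip(
        np.round((x - grid[0]) / (grid[1] - grid[0])).astype(int), 0, len(grid) - 1
    )
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    np.add.at(sums, idx, y)
    np.add.at(counts, idx, 1.0)
    return sums, counts


def bin_points_2d(s, t, v, grid):
    """Accumulate (s, t, v) onto the grid x grid lattice; (sums, counts)."""
    step = grid[1] - grid[0]
    si = np.clip(np.round((np.asarray(s, float) - grid[0]) / step).astype(int),
                 0, len(grid) - 1)
    ti = np.clip(np.round((np.asarray(t, float) - grid[0]) / step).astype(int),
                 0, len(grid) - 1)
    sums = np.zeros((len(grid), len(grid)))
    counts = np.zeros((len(grid), len(grid)))
    np.add.at(sums, (si, ti), np.asarray(v, float))
    np.add.at(counts, (si, ti), 1.0)
    return sums, counts


def _kernel_moment_matrices(grid, bandwidth):
    """K_a[i, j] = k((g_j - g_i)/h) * (g_j - g_i)^a for a = 0, 1, 2."""
    d = grid[None, :] - grid[:, None]
    k = np.exp(-0.5 * (d / bandwidth) ** 2)
    return k, k * d, k * d * d


def local_linear_1d(grid, sums, counts, bandwidth):
    """Local-linear estimate on the grid from binned data.

    ``sums``/``counts`` as returned by :func:`bin_points_1d`; empty bins carry
    zero weight. Returns the fitted values at every grid point.
    """
    k0, k1, k2 = _kernel_moment_matrices(grid, bandwidth)
    w = counts
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    s0 = k0 @ w
    s1 = k1 @ w
    s2 = k2 @ w
    t0 = k0 @ (w * means)
    t1 = k1 @ (w * means)
    denom = s0 * s2 - s1**2
    est = np.where(
        np.abs(denom) > _RIDGE,
        (s2 * t0 - s1 * t1) / np.where(np.abs(denom) > _RIDGE, denom, 1.0),
        np.divide(t0, s0, out=np.zeros_like(t0), where=s0 > _RIDGE),
    )
    return est


def local_linear_2d(grid, sums, counts, bandwidth):
    """Local-linear surface estimate on grid x grid from binned data.

    Uses the separability of the Gaussian product kernel on the lattice: every
    moment is a pair of small matrix products, and the per-target 3x3 normal
    equations are solved in a single batched call.
    """
    k = _kernel_moment_matrices(grid, bandwidth)
    w = counts
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    wv = w * means

    def mom(a, b, mat):
        return k[a] @ mat @ k[b].T

    s00, s10, s01 = mom(0, 0, w), mom(1, 0, w), mom(0, 1, w)
    s20, s11, s02 = mom(2, 0, w), mom(1, 1, w), mom(0, 2, w)
    t00, t10, t01 = mom(0, 0, wv), mom(1, 0, wv), mom(0, 1, wv)

    g = len(grid)
    lhs = np.empty((g * g, 3, 3))
    lhs[:, 0, 0] = s00.ravel()
    lhs[:, 0, 1] = lhs[:, 1, 0] = s10.ravel()
    lhs[:, 0, 2] = lhs[:, 2, 0] = s01.ravel()
    lhs[:, 1, 1] = s20.ravel()
    lhs[:, 1, 2] = lhs[:, 2, 1] = s11.ravel()
    lhs[:, 2, 2] = s02.ravel()
    lhs += _RIDGE * np.eye(3)
    rhs = np.stack([t00.ravel(), t10.ravel(), t01.ravel()], axis=1)
    beta = np.linalg.solve(lhs, rhs[..., None])[:, 0, 0]
    return beta.reshape(g, g)
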