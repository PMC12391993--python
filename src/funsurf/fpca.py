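"""Sparse functional principal component analysis for one longitudinal marker.

The estimator follows the conditional-expectation (PACE) route for sparse,
irregular, noisy curves: pool all subjects' observations to smooth a mean
function; smooth the off-diagonal raw covariances onto a grid surface to
obtain the latent-process covariance (the diagonal is inflated by measurement
error, which is estimated from the gap between the smoothed raw variance and
the surface diagonal); eigendecompose the surface under trapezoid quadrature;
and recover per-subject scores as best linear unbiased predictors given each
subject's own sparse observations.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator

from .smoothing import bin_points_1d, bin_points_2d, local_linear_1d, local_linear_2d

_VALID_TRANSFORMS = ("none", "z", "log1p-z")


class FpcaError(RuntimeError):
    """The marker data cannot support the requested fit."""


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return w


def _fix_signs(phi: np.ndarray) -> np.ndarray:
    # flip each column so its entry of maximal magnitude is positive
    idx = np.argmax(np.abs(phi), axis=0)
    signs = np.sign(phi[idx, np.arange(phi.shape[1])])
    signs[signs == 0] = 1.0
    return phi * signs


class UnivariateFPCA(BaseEstimator):
    """PACE-style FPCA for one sparsely observed marker.

    Parameters
    ----------
    grid_size : number of equispaced grid points on ``t_range``.
    t_range : observation window in months.
    bandwidth : Gaussian kernel bandwidth (months) of the covariance smoother.
    mean_lambda : smoothing-spline penalty for the mean; ``None`` selects it
        by generalized cross-validation.
    pve : per-marker proportion-of-variance threshold for retaining
        components.
    max_components : hard cap on retained components.
    pre_transform : pre-transform, one of ``'none'``, ``'z'`` (center/scale) or
        ``'log1p-z'`` (log1p then center/scale, for right-skewed markers).

    Attributes (after fit)
    ----------------------
    grid_, mean_ : analysis grid and mean function values on it.
    eigenfunctions_ : (grid_size, n_components_) orthonormal under trapezoid
        quadrature, signs fixed.
    eigenvalues_ : retained eigenvalues, decreasing.
    noise_variance_ : measurement-error variance (floored at 0).
    pve_ : cumulative proportion of variance explained (all positive
        eigenvalues).
    """

    def __init__(
        self,
        grid_size: int = 51,
        t_range: tuple = (0.0, 12.0),
        bandwidth: float = 1.5,
        mean_lambda: float | None = None,
        pve: float = 0.99,
        max_components: int = 5,
        pre_transform: str = "z",
    ):
        self.grid_size = grid_size
        self.t_range = t_range
        self.bandwidth = bandwidth
        self.mean_lambda = mean_lambda
        self.pve = pve
        self.max_components = max_components
        self.pre_transform = pre_transform

    # -- pre-transform ------------------------------------------------------

    def _apply_transform(self, values: np.ndarray) -> np.ndarray:
        if self.pre_transform == "none":
            return values
        v = values
        if self.pre_transform == "log1p-z":
            if np.any(v <= -1):
                raise FpcaError("log1p transform requires values > -1")
            v = np.log1p(v)
        return (v - self.transform_center_) / self.transform_scale_

    def _fit_transform_params(self, pooled: np.ndarray):
        if self.pre_transform not in _VALID_TRANSFORMS:
            raise ValueError(f"transform must be one of {_VALID_TRANSFORMS}")
        if self.pre_transform == "none":
            self.transform_center_, self.transform_scale_ = 0.0, 1.0
            return
        v = np.log1p(pooled) if self.pre_transform == "log1p-z" else pooled
        if self.pre_transform == "log1p-z" and np.any(pooled <= -1):
            raise FpcaError("log1p transform requires values > -1")
        self.transform_center_ = float(np.mean(v))
        scale = float(np.std(v))
        self.transform_scale_ = scale if scale > 0 else 1.0

    # -- fitting steps ------------------------------------------------------

    def _estimate_mean(self, times, values):
        distinct = np.unique(times)
        if distinct.size < 4:
            raise FpcaError(
                f"mean estimation needs >= 4 distinct times, got {distinct.size}"
            )
        # bin pooled points onto grid cells to keep GCV cheap; using the
        # within-bin mean time (not the cell center) keeps data that lie on a
        # line exactly linear, which the spline then reproduces exactly
        step = self.grid_[1] - self.grid_[0]
        idx = np.clip(
            np.round((times - self.grid_[0]) / step).astype(int),
            0, self.grid_.size - 1,
        )
        counts = np.bincount(idx, minlength=self.grid_.size).astype(float)
        t_sums = np.bincount(idx, weights=times, minlength=self.grid_.size)
        v_sums = np.bincount(idx, weights=values, minlength=self.grid_.size)
        occupied = counts > 0
        if self.bandwidth == 0:  # dense common-grid mode: raw column means
            if not occupied.all():
                raise FpcaError(
                    "bandwidth=0 (no smoothing) requires every grid cell "
                    "to be observed"
                )
            return v_sums / counts
        t_bin = t_sums[occupied] / counts[occupied]
        v_bin = v_sums[occupied] / counts[occupied]
        w_bin = counts[occupied]
        if t_bin.size >= 5:
            spline = make_smoothing_spline(t_bin, v_bin, w=w_bin, lam=self.mean_lambda)
            est = np.asarray(spline(self.grid_))
        else:  # too few occupied cells for a cubic spline: weighted line fit
            coef = np.polyfit(t_bin, v_bin, deg=1, w=np.sqrt(w_bin))
            est = np.polyval(coef, self.grid_)
        return est

    def _estimate_covariance(self, times_list, values_list):
        """Smooth off-diagonal raw covariances; returns (surface, sigma^2).

        With ``bandwidth == 0`` no smoothing is applied: all raw products
        (including same-time ones) are binned and averaged — the empirical
        covariance, appropriate for noiseless dense common-grid designs only.
        """
        dense = self.bandwidth == 0
        s_all, t_all, prod_all = [], [], []
        d_t, d_sq = [], []
        any_pairs = False
        for t, r in zip(times_list, values_list):
            n = len(t)
            if n == 0:
                continue
            d_t.append(t)
            d_sq.append(r * r)
            if n >= 2:
                any_pairs = True
                ti = np.repeat(t, n)
                tj = np.tile(t, n)
                pi = np.repeat(r, n) * np.tile(r, n)
                keep = slice(None) if dense else ti != tj
                s_all.append(ti[keep])
                t_all.append(tj[keep])
                prod_all.append(pi[keep])
        if not any_pairs:
            raise FpcaError(
                "covariance unidentifiable: no subject has >= 2 observations"
            )
        s = np.concatenate(s_all)
        t = np.concatenate(t_all)
        p = np.concatenate(prod_all)
        sums, counts = bin_points_2d(s, t, p, self.grid_)
        if dense:
            if (counts == 0).any():
                raise FpcaError(
                    "bandwidth=0 (no smoothing) requires a fully occupied "
                    "grid x grid design"
                )
            surface = sums / counts
        else:
            surface = local_linear_2d(self.grid_, sums, counts, self.bandwidth)
        surface = 0.5 * (surface + surface.T)

        # measurement-error variance: smoothed raw variance minus the surface
        # diagonal, averaged over the central half of the window
        dsum, dcount = bin_points_1d(
            np.concatenate(d_t), np.concatenate(d_sq), self.grid_
        )
        if dense:
            raw_var = np.divide(
                dsum, dcount, out=np.zeros_like(dsum), where=dcount > 0
            )
        else:
            raw_var = local_linear_1d(self.grid_, dsum, dcount, self.bandwidth)
        g = self.grid_
        central = (g >= g[0] + (g[-1] - g[0]) / 4) & (g <= g[-1] - (g[-1] - g[0]) / 4)
        sigma2 = float(np.mean(raw_var[central] - np.diag(surface)[central]))
        return surface, max(sigma2, 0.0)

    def _eigendecompose(self, surface):
        if not np.all(np.isfinite(surface)):
            raise FpcaError("covariance surface contains non-finite entries")
        w = trapezoid_weights(self.grid_)
        sw = np.sqrt(w)
        a = sw[:, None] * surface * sw[None, :]
        evals, evecs = np.linalg.eigh(a)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        phi = evecs[:, order] / sw[:, None]
        return _fix_signs(phi), evals

    # -- public API ---------------------------------------------------------

    def fit(self, times_list, values_list):
        """Fit from per-subject observation arrays.

        ``times_list[i]`` and ``values_list[i]`` are 1-d arrays of subject i's
        observation times (months) and raw marker values; empty arrays are
        allowed (the subject contributes nothing to the fit).
        """
        lo, hi = self.t_range
        self.grid_ = np.linspace(lo, hi, self.grid_size)
        times_list = [np.asarray(t, float) for t in times_list]
        values_list = [np.asarray(v, float) for v in values_list]
        pooled_t = np.concatenate([t for t in times_list if len(t)]) if any(
            len(t) for t in times_list
        ) else np.array([])
        if pooled_t.size and (pooled_t.min() < lo - 1e-9 or pooled_t.max() > hi + 1e-9):
            raise FpcaError(f"observation times outside [{lo}, {hi}]")
        pooled_v = np.concatenate([v for v in values_list if len(v)])
        self._fit_transform_params(pooled_v)
        z_list = [self._apply_transform(v) if len(v) else v for v in values_list]
        pooled_z = np.concatenate([z for z in z_list if len(z)])

        self.mean_ = self._estimate_mean(pooled_t, pooled_z)
        centered = [
            z - np.interp(t, self.grid_, self.mean_) if len(t) else z
            for t, z in zip(times_list, z_list)
        ]
        surface, sigma2 = self._estimate_covariance(times_list, centered)
        self.covariance_ = surface
        self.noise_variance_ = sigma2

        phi, evals = self._eigendecompose(surface)
        positive = evals > max(evals[0], 0) * 1e-10
        evals_pos = evals[positive]
        if evals_pos.size == 0:
            raise FpcaError("covariance surface has no positive eigenvalues")
        self.pve_ = np.cumsum(evals_pos) / np.sum(evals_pos)
        m = int(np.searchsorted(self.pve_, self.pve - 1e-12) + 1)
        m = min(m, self.max_components, evals_pos.size)
        self.n_components_ = m
        self.eigenvalues_ = evals_pos[:m]
        self.eigenfunctions_ = phi[:, positive][:, :m]
        return self

    def _phi_at(self, t):
        return np.column_stack(
            [
                np.interp(t, self.grid_, self.eigenfunctions_[:, k])
                for k in range(self.n_components_)
            ]
        )

    def conditional_scores(self, times, values):
        """BLUP scores for one subject: Lambda Phi' Sigma_y^{-1} (y - mu).

        A subject with no observations gets the prior mean (zeros); callers
        can detect this via the returned ``observed`` flag.
        """
        t = np.asarray(times, float)
        if t.size == 0:
            return np.zeros(self.n_components_), False
        lo, hi = self.t_range
        if t.min() < lo - 1e-9 or t.max() > hi + 1e-9:
            raise FpcaError(f"observation times outside [{lo}, {hi}]")
        z = self._apply_transform(np.asarray(values, float))
        resid = z - np.interp(t, self.grid_, self.mean_)
        phi = self._phi_at(t)
        lam = self.eigenvalues_
        sigma_y = (phi * lam) @ phi.T + self.noise_variance_ * np.eye(t.size)
        # tiny jitter keeps the system solvable in the noiseless dense limit
        sigma_y[np.diag_indices_from(sigma_y)] += 1e-10 * (1.0 + lam[0])
        xi = lam * (phi.T @ np.linalg.solve(sigma_y, resid))
        return xi, True

    def transform(self, times_list, values_list):
        """Score matrix (n_subjects, n_components_); zeros for empty subjects."""
        out = np.zeros((len(times_list), self.n_components_))
        flags = np.zeros(len(times_list), dtype=bool)
        for i, (t, v) in enumerate(zip(times_list, values_list)):
            out[i], flags[i] = self.conditional_scores(t, v)
        return out, flags

    def to_dict(self) -> dict:
        """JSON-serializable representation of the fit."""
        return {
            "grid": self.grid_.tolist(),
            "mean": self.mean_.tolist(),
            "eigenfunctions": self.eigenfunctions_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "noise_variance": self.noise_variance_,
            "pve": self.pve_.tolist(),
            "transform": {
                "kind": self.pre_transform,
                "center": self.transform_center_,
                "scale": self.transform_scale_,
            },
        }
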