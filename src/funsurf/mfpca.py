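"""Multivariate functional PCA over the marker panel.

Univariate FPCA scores are estimated marker by marker, stacked, and the
eigendecomposition of their sample covariance yields multivariate components
(the score-space construction of multivariate FPCA for sparse data). A
subject's multivariate score is the projection of their stacked univariate
score vector onto the leading eigenvectors; the number of retained components
is the smallest count whose cumulative proportion of explained variance
reaches a threshold (0.97 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fpca import FpcaError, UnivariateFPCA, _fix_signs
from .markers import marker_transform_rules


def select_components(pve_cumulative, threshold: float = 0.97) -> int:
    """Smallest m whose cumulative PVE reaches ``threshold`` (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    pve = np.asarray(pve_cumulative, float)
    if threshold >= 1.0:
        return int(pve.size)
    return int(np.searchsorted(pve, threshold - 1e-12) + 1)


class MFPCA(BaseEstimator):
    """Multivariate FPCA on a long-format longitudinal table.

    Parameters mirror :class:`~funsurf.fpca.UnivariateFPCA` where they are
    passed through per marker. ``transforms`` maps marker name to a
    pre-transform ('none' | 'z' | 'log1p-z'); unspecified markers follow
    :func:`funsurf.markers.marker_transform_rules`.

    Attributes (after fit)
    ----------------------
    marker_names_, subject_ids_ : panel and training order.
    univariate_fits_ : dict marker -> fitted UnivariateFPCA.
    c_vectors_ : (D, n_components_) orthonormal eigenvectors of the stacked
        score covariance (D = total univariate components).
    eigenvalues_ : multivariate eigenvalues (all D, decreasing, >= 0).
    pve_cumulative_, n_components_ : selection bookkeeping.
    scores_ : (n_subjects, n_components_) training scores.
    """

    def __init__(
        self,
        pve: float = 0.97,
        n_components: int | None = None,
        pve_univariate: float = 0.99,
        max_univariate_components: int = 5,
        grid_size: int = 51,
        t_range: tuple = (0.0, 12.0),
        bandwidth: float = 1.5,
        mean_lambda: float | None = None,
        transforms: dict | None = None,
    ):
        self.pve = pve
        self.n_components = n_components
        self.pve_univariate = pve_univariate
        self.max_univariate_components = max_univariate_components
        self.grid_size = grid_size
        self.t_range = t_range
        self.bandwidth = bandwidth
        self.mean_lambda = mean_lambda
        self.transforms = transforms

    @staticmethod
    def _as_long_frame(X) -> pd.DataFrame:
        if hasattr(X, "longitudinal_frame"):
            return X.longitudinal_frame()
        return X

    def _marker_arrays(self, frame, subject_ids, marker, landmark=None):
        sub = frame[frame["marker"] == marker]
        if landmark is not None:
            sub = sub[sub["time_months"] <= landmark]
        grouped = {
            sid: (g["time_months"].to_numpy(float), g["value"].to_numpy(float))
            for sid, g in sub.groupby("subject_id")
        }
        empty = (np.array([]), np.array([]))
        times, values = [], []
        for sid in subject_ids:
            t, v = grouped.get(sid, empty)
            order = np.argsort(t)
            times.append(t[order])
            values.append(v[order])
        return times, values

    def fit(self, X, y=None):
        """Fit on a Cohort or a long DataFrame
        (columns subject_id, marker, time_months, value)."""
        frame = self._as_long_frame(X)
        if hasattr(X, "marker_names"):
            self.marker_names_ = list(X.marker_names)
        else:
            self.marker_names_ = sorted(frame["marker"].unique())
        if hasattr(X, "subject_ids"):
            self.subject_ids_ = X.subject_ids()
        else:
            self.subject_ids_ = sorted(frame["subject_id"].unique())

        rules = marker_transform_rules(self.marker_names_)
        if self.transforms:
            rules.update(self.transforms)

        self.univariate_fits_ = {}
        blocks = []
        for marker in self.marker_names_:
            times, values = self._marker_arrays(frame, self.subject_ids_, marker)
            fit = UnivariateFPCA(
                grid_size=self.grid_size,
                t_range=self.t_range,
                bandwidth=self.bandwidth,
                mean_lambda=self.mean_lambda,
                pve=self.pve_univariate,
                max_components=self.max_univariate_components,
                pre_transform=rules[marker],
            )
            try:
                fit.fit(times, values)
            except FpcaError as err:
                raise FpcaError(f"marker {marker!r}: {err}") from err
            self.univariate_fits_[marker] = fit
            xi, _ = fit.transform(times, values)
            blocks.append(xi)

        stacked = np.hstack(blocks)  # (n, D)
        self.block_sizes_ = [b.shape[1] for b in blocks]
        cov = np.cov(stacked, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        self.eigenvalues_ = np.clip(evals[order], 0.0, None)
        self.c_vectors_full_ = _fix_signs(evecs[:, order])
        total = self.eigenvalues_.sum()
        self.pve_cumulative_ = np.cumsum(self.eigenvalues_) / total
        if self.n_components is not None:
            m = int(self.n_components)
        else:
            m = select_components(self.pve_cumulative_, self.pve)
        m = max(1, min(m, self.eigenvalues_.size))
        self.n_components_ = m
        self.c_vectors_ = self.c_vectors_full_[:, :m]
        self.scores_ = stacked @ self.c_vectors_
        self.stacked_scores_ = stacked
        return self

    def _stacked_scores(self, frame, subject_ids, landmark=None):
        blocks, flags = [], []
        for marker in self.marker_names_:
            times, values = self._marker_arrays(frame, subject_ids, marker, landmark)
            xi, flag = self.univariate_fits_[marker].transform(times, values)
            blocks.append(xi)
            flags.append(flag)
        observed_any = np.column_stack(flags).any(axis=1)
        return np.hstack(blocks), observed_any

    def transform(self, X, landmark: float | None = None) -> pd.DataFrame:
        """Project subjects onto the fitted components.

        Only measurements at or before ``landmark`` (months) are used when it
        is given; subjects with no usable measurement get prior-mean (zero)
        scores and ``sparse_flag=True``.
        """
        if landmark is not None and not (self.t_range[0] <= landmark <= self.t_range[1]):
            raise ValueError(
                f"landmark must lie in {self.t_range}, got {landmark}"
            )
        frame = self._as_long_frame(X)
        if hasattr(X, "subject_ids"):
            subject_ids = X.subject_ids()
        else:
            subject_ids = list(pd.unique(frame["subject_id"]))
        stacked, observed = self._stacked_scores(frame, subject_ids, landmark)
        scores = stacked @ self.c_vectors_
        out = pd.DataFrame(
            scores,
            index=pd.Index(subject_ids, name="subject_id"),
            columns=[f"mfpc_{k + 1}" for k in range(self.n_components_)],
        )
        out["sparse_flag"] = ~observed
        if landmark is not None:
            out.attrs["landmark"] = landmark
        return out

    def to_dict(self) -> dict:
        return {
            "marker_names": self.marker_names_,
            "block_sizes": self.block_sizes_,
            "c_vectors": self.c_vectors_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "pve_cumulative": self.pve_cumulative_.tolist(),
            "n_components": self.n_components_,
            "univariate_fits": {
                m: f.to_dict() for m, f in self.univariate_fits_.items()
            },
        }
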