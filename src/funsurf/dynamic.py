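"""Personalized dynamic prediction by landmarking.

A single model is trained on full-window (12-month) information; at a landmark
time s the subject's MFPC scores are re-estimated from measurements observed
up to s only, features are rebuilt, and the conditional event-free probability
is S(t)/S(s) from the forest's predicted curve. A cubic-spline smoothed,
re-monotonized copy of each curve is kept for display; all metrics use the raw
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .cohort import Cohort, SubjectRecord
from .forest import FeatureEncoder, SurvivalForest, build_feature_matrix
from .mfpca import MFPCA

HORIZON_MONTHS = 60.0


class NumericalFloorError(RuntimeError):
    """S(s) is numerically zero; conditioning is not meaningful."""


@dataclass
class DynamicPrediction:
    """Conditional survival for one subject at one landmark."""

    subject_id: str
    landmark: float
    times: np.ndarray          # horizon grid, t >= landmark
    survival: np.ndarray       # raw conditional S(t | s)
    smoothed: np.ndarray       # display curve (cubic spline, re-monotonized)
    variant: str
    scores: pd.Series | None = None
    sparse_flag: bool = False
    meta: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "landmark": self.landmark,
                "time_months": self.times,
                "conditional_survival": self.survival,
                "smoothed": self.smoothed,
            }
        )


def _smooth_display_curve(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    if times.size < 3:
        return values.copy()
    spline = CubicSpline(times, values, bc_type="natural")
    smoothed = np.clip(spline(times), 0.0, 1.0)
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    return iso.fit_transform(times, smoothed)


class FunctionalSurvivalForest(BaseEstimator):
    """End-to-end estimator: MFPCA feature extraction + random survival forest.

    ``variant`` selects the feature block: 'A' clinicopathologic covariates
    only, 'B' adds preoperative marker values, 'C' adds MFPC scores of the
    longitudinal markers. ``outcome`` is 'pfs' or 'os'.
    """

    def __init__(
        self,
        variant: str = "C",
        outcome: str = "pfs",
        pve: float = 0.97,
        n_components: int | None = None,
        pve_univariate: float = 0.99,
        max_univariate_components: int = 5,
        bandwidth: float = 1.5,
        mean_lambda: float | None = None,
        transforms: dict | None = None,
        n_trees: int = 1000,
        min_samples_leaf: int = 15,
        max_features: str | float = "sqrt",
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.variant = variant
        self.outcome = outcome
        self.pve = pve
        self.n_components = n_components
        self.pve_univariate = pve_univariate
        self.max_univariate_components = max_univariate_components
        self.bandwidth = bandwidth
        self.mean_lambda = mean_lambda
        self.transforms = transforms
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, cohort: Cohort, y=None):
        self.marker_names_ = tuple(cohort.marker_names)
        self.mfpca_ = None
        scores = None
        if self.variant == "C":
            self.mfpca_ = MFPCA(
                pve=self.pve,
                n_components=self.n_components,
                pve_univariate=self.pve_univariate,
                max_univariate_components=self.max_univariate_components,
                bandwidth=self.bandwidth,
                mean_lambda=self.mean_lambda,
                transforms=self.transforms,
            ).fit(cohort)
            scores = self.mfpca_.transform(cohort)
        raw = build_feature_matrix(cohort, scores, self.variant)
        self.encoder_ = FeatureEncoder().fit(raw)
        X = self.encoder_.transform(raw)
        times, events = cohort.outcome_arrays(self.outcome)
        self.forest_ = SurvivalForest(
            n_trees=self.n_trees,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        ).fit(X, times, events)
        self.feature_frame_ = X
        return self

    # -- feature assembly for arbitrary subjects ----------------------------

    def _features_for(self, cohort: Cohort, landmark: float | None = None):
        scores = None
        sparse = pd.Series(False, index=cohort.subject_ids())
        if self.variant == "C":
            scores = self.mfpca_.transform(cohort, landmark=landmark)
            sparse = scores["sparse_flag"]
        raw = build_feature_matrix(cohort, scores, self.variant)
        return self.encoder_.transform(raw), scores, sparse

    def predict_survival(self, cohort: Cohort, time_grid=None) -> np.ndarray:
        X, _, _ = self._features_for(cohort)
        return self.forest_.predict_survival(X, time_grid)

    def predict_risk(self, cohort: Cohort, horizon: float) -> np.ndarray:
        X, _, _ = self._features_for(cohort)
        return self.forest_.predict_risk(X, horizon)

    # -- landmarking ---------------------------------------------------------

    def predict_conditional(
        self,
        subject: SubjectRecord,
        landmark: float,
        horizon_grid=None,
        floor: float = 1e-6,
    ) -> DynamicPrediction:
        """Conditional survival S(t | s) for one subject, landmark s.

        Scores (variant C) are re-estimated from measurements with time <= s;
        the caller asserts the subject is event-free at s.
        """
        if not 0 <= landmark <= 12:
            raise ValueError(f"landmark must be in [0, 12] months, got {landmark}")
        if horizon_grid is None:
            horizon_grid = np.linspace(landmark, HORIZON_MONTHS, 121)
        grid = np.asarray(horizon_grid, float)
        if (grid < landmark - 1e-9).any():
            raise ValueError("horizon grid must start at or after the landmark")

        mini = Cohort([subject], marker_names=self.marker_names_)
        X, scores, sparse = self._features_for(mini, landmark=landmark)
        s_at = self.forest_.predict_survival(X, np.array([landmark]))[0, 0]
        if s_at < floor:
            raise NumericalFloorError(
                f"predicted S({landmark}) = {s_at:.3g} below floor {floor}"
            )
        s_grid = self.forest_.predict_survival(X, grid)[0]
        cond = np.clip(s_grid / s_at, 0.0, 1.0)
        cond[np.isclose(grid, landmark)] = 1.0
        return DynamicPrediction(
            subject_id=subject.subject_id,
            landmark=float(landmark),
            times=grid,
            survival=cond,
            smoothed=_smooth_display_curve(grid, cond),
            variant=self.variant,
            scores=scores.iloc[0] if scores is not None else None,
            sparse_flag=bool(sparse.iloc[0]),
            meta={"outcome": self.outcome, "s_at_landmark": float(s_at)},
        )

    def prediction_sequence(
        self, subject: SubjectRecord, visit_times, horizon: float = HORIZON_MONTHS
    ) -> list[DynamicPrediction]:
        """One updated prediction per visit, each using data up to that visit."""
        visits = list(visit_times)
        if visits != sorted(visits):
            raise ValueError("visit_times must be sorted ascending")
        out = []
        for s in visits:
            grid = np.linspace(s, horizon, 121)
            out.append(self.predict_conditional(subject, s, grid))
        return out
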