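"""Random survival forests on clinicopathologic covariates and MFPC scores.

Three feature variants are supported, mirroring a nested-model comparison:
A = baseline clinicopathologic covariates only, B = A plus the preoperative
(t=0) value of each analysis marker, C = A plus the multivariate functional
principal component scores. The ensemble itself is scikit-survival's
RandomSurvivalForest (log-rank splitting, Nelson-Aalen terminal estimates,
out-of-bag concordance); this module adds the feature schema/imputation
contract, monotone survival-curve prediction on arbitrary grids, and grouped
permutation variable importance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv


class FeatureSchemaError(ValueError):
    """Prediction-time features do not match the fitted schema."""


class FeatureEncoder:
    """Deterministic encoding + training-set imputation of a feature frame.

    Numeric columns pass through with median imputation; categorical/object
    columns are one-hot encoded against the categories seen at fit time
    (unseen levels map to all-zero rows with a warning); binary 0/1 columns
    stay single columns with mode imputation.
    """

    def fit(self, frame: pd.DataFrame) -> "FeatureEncoder":
        self.columns_ = list(frame.columns)
        self.categories_ = {}
        self.fill_ = {}
        for col in frame.columns:
            s = frame[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                cats = sorted(s.dropna().astype(str).unique())
                self.categories_[col] = cats
                mode = s.dropna().astype(str).mode()
                self.fill_[col] = mode.iloc[0] if len(mode) else (cats[0] if cats else "")
            else:
                med = s.median()
                self.fill_[col] = float(med) if pd.notna(med) else 0.0
        self.encoded_columns_ = list(self._encode(frame, check=False).columns)
        return self

    def _encode(self, frame: pd.DataFrame, check: bool = True) -> pd.DataFrame:
        if check:
            missing = set(self.columns_) - set(frame.columns)
            extra = set(frame.columns) - set(self.columns_)
            if missing or extra:
                raise FeatureSchemaError(
                    f"feature schema mismatch: missing={sorted(missing)}, "
                    f"extra={sorted(extra)}"
                )
        pieces = []
        for col in self.columns_:
            s = frame[col]
            if col in self.categories_:
                s = s.astype(str).where(s.notna(), self.fill_[col])
                unseen = set(s.unique()) - set(self.categories_[col])
                if unseen and check:
                    warnings.warn(
                        f"column {col!r}: unseen categories {sorted(unseen)} "
                        "encoded as all-zero",
                        UserWarning,
                    )
                for cat in self.categories_[col]:
                    pieces.append(
                        pd.Series((s == cat).astype(float), name=f"{col}={cat}")
                    )
            else:
                filled = pd.to_numeric(s, errors="coerce").fillna(self.fill_[col])
                pieces.append(pd.Series(filled.astype(float), name=col))
        out = pd.concat(pieces, axis=1)
        out.index = frame.index
        return out

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = self._encode(frame, check=True)
        return out[self.encoded_columns_]


def build_feature_matrix(
    cohort,
    scores: pd.DataFrame | None = None,
    variant: str = "A",
) -> pd.DataFrame:
    """Assemble the raw (pre-encoding) feature frame for one model variant.

    Variant A: the baseline clinicopathologic covariates. Variant B adds the
    preoperative (t=0) value of each analysis marker (columns ``preop_<m>``).
    Variant C adds the MFPC score columns from ``scores`` (a DataFrame indexed
    by subject_id; its ``sparse_flag`` column is dropped).
    """
    if variant not in ("A", "B", "C"):
        raise ValueError(f"variant must be 'A', 'B' or 'C', got {variant!r}")
    base = cohort.baseline_frame().set_index("subject_id")
    if variant == "A":
        return base
    if variant == "B":
        preop = {}
        for s in cohort.subjects:
            row = {}
            for marker in cohort.marker_names:
                t, v = s.marker_observations(marker)
                at0 = v[t == 0]
                row[f"preop_{marker}"] = float(at0[0]) if at0.size else np.nan
            preop[s.subject_id] = row
        preop_frame = pd.DataFrame.from_dict(preop, orient="index")
        preop_frame.index.name = "subject_id"
        return base.join(preop_frame)
    if scores is None:
        raise ValueError("variant C requires MFPC scores")
    score_cols = scores.drop(columns=["sparse_flag"], errors="ignore")
    return base.join(score_cols)


class SurvivalForest(BaseEstimator):
    """Random survival forest with a fixed feature schema.

    Thin estimator over scikit-survival's RandomSurvivalForest: log-rank
    splits, Nelson-Aalen terminal estimates, bootstrap resampling, out-of-bag
    concordance stored as ``oob_cindex_``. ``min_samples_leaf`` plays the role
    of a minimum terminal node size.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        max_features: str | float = "sqrt",
        min_samples_leaf: int = 15,
        max_depth: int | None = None,
        bootstrap: bool = True,
        random_state: int = 0,
        n_jobs: int = 1,
        max_grid_points: int = 200,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.bootstrap = bootstrap
        self.random_state = random_state
        self.n_jobs = n_jobs
        self.max_grid_points = max_grid_points

    def fit(self, X: pd.DataFrame, times, events):
        times = np.asarray(times, float)
        events = np.asarray(events, bool)
        if (times <= 0).any():
            raise ValueError("all survival times must be positive")
        n_events = int(events.sum())
        if n_events == 0:
            raise ValueError("cannot fit a survival forest on all-censored data")
        if n_events < 20:
            warnings.warn(
                f"only {n_events} events; forest estimates will be unstable",
                UserWarning,
            )
        self.feature_names_ = list(X.columns)
        self.model_ = RandomSurvivalForest(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            max_depth=self.max_depth,
            bootstrap=self.bootstrap,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
            oob_score=self.bootstrap and n_events >= 2,
        )
        y = Surv.from_arrays(events, times)
        self.model_.fit(X.to_numpy(float), y)
        self.oob_cindex_ = float(getattr(self.model_, "oob_score_", np.nan))
        event_times = np.unique(times[events])
        if event_times.size > self.max_grid_points:
            q = np.linspace(0, 1, self.max_grid_points)
            event_times = np.unique(np.quantile(event_times, q))
        self.event_times_ = event_times
        self.train_times_ = times
        self.train_events_ = events
        return self

    def _check_schema(self, X: pd.DataFrame):
        if list(X.columns) != self.feature_names_:
            missing = set(self.feature_names_) - set(X.columns)
            extra = set(X.columns) - set(self.feature_names_)
            raise FeatureSchemaError(
                f"feature columns do not match fit schema: missing="
                f"{sorted(missing)}, extra={sorted(extra)}"
            )

    def predict_survival(self, X: pd.DataFrame, time_grid=None) -> np.ndarray:
        """Per-subject survival curves on ``time_grid`` (default: event times).

        Curves are right-continuous step functions with S(0) = 1, evaluated by
        last-value interpolation; monotone non-increasing by construction.
        """
        self._check_schema(X)
        grid = np.asarray(
            self.event_times_ if time_grid is None else time_grid, float
        )
        fns = self.model_.predict_survival_function(
            X.to_numpy(float), return_array=True
        )
        model_times = self.model_.unique_times_
        idx = np.searchsorted(model_times, grid + 1e-12) - 1
        out = np.where(idx[None, :] >= 0, fns[:, np.clip(idx, 0, None)], 1.0)
        return np.clip(out, 0.0, 1.0)

    def predict_risk(self, X: pd.DataFrame, horizon: float) -> np.ndarray:
        """Predicted event probability by ``horizon``: 1 - S(horizon)."""
        return 1.0 - self.predict_survival(X, np.array([horizon]))[:, 0]

    def predict_ensemble_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Aggregate risk score (sum of the ensemble cumulative hazard)."""
        self._check_schema(X)
        return self.model_.predict(X.to_numpy(float))


def variable_importance(
    forest: SurvivalForest,
    X: pd.DataFrame,
    times,
    events,
    n_permutations: int = 5,
    seed: int = 0,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Permutation variable importance on concordance error.

    For each feature (or named group of columns, permuted jointly — e.g. all
    one-hot columns of one covariate, or all scores of one component), the
    importance is the mean increase in prediction error (1 - Harrell C of the
    ensemble risk score) over ``n_permutations`` seeded permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    rng = np.random.default_rng(seed)
    y_args = (events, times)

    def error(frame):
        risk = forest.predict_ensemble_risk(frame)
        c = concordance_index_censored(*y_args, risk)[0]
        return 1.0 - c

    base_error = error(X)
    if groups is None:
        groups = {name: [name] for name in X.columns}
    rows = []
    for name, cols in groups.items():
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise FeatureSchemaError(f"group {name!r}: unknown columns {missing}")
        increases = []
        for _ in range(n_permutations):
            perm = rng.permutation(len(X))
            shuffled = X.copy()
            shuffled[cols] = X[cols].to_numpy()[perm]
            increases.append(error(shuffled) - base_error)
        rows.append((name, float(np.mean(increases))))
    table = pd.DataFrame(rows, columns=["feature", "vimp"])
    return table.sort_values("vimp", ascending=False).reset_index(drop=True)
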