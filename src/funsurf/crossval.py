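"""Repeated stratified cross-validation and external validation.

Fold honesty: every training fold refits the whole feature pipeline — marker
transforms, univariate FPCA, multivariate component selection (the 97% rule),
imputation — and held-out subjects are only ever projected through the
fold-fitted objects. Metrics are computed per fold with censoring weights
estimated on the training portion, then averaged over folds and repeats.
"""

from __future__ import annotations

import hashlib
import pickle

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort
from .dynamic import FunctionalSurvivalForest
from .metrics import (
    UndefinedMetricError,
    brier_score,
    censoring_weights,
    time_dependent_auc,
)

DEFAULT_HORIZONS = (12.0, 36.0, 60.0)
EARLY_RECURRENCE_CUTOFF = 13.0


def make_folds(cohort: Cohort, outcome: str, k: int, repeats: int, seed: int):
    """Fold plan: list over repeats of (train_ids, test_ids) pairs,
    stratified by the event indicator."""
    ids = np.array(cohort.subject_ids())
    _, events = cohort.outcome_arrays(outcome)
    plan = []
    for r in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        folds = [
            (ids[tr].tolist(), ids[te].tolist())
            for tr, te in splitter.split(ids, events.astype(int))
        ]
        plan.append(folds)
    return plan


def _model_fingerprint(model: FunctionalSurvivalForest) -> str:
    payload = pickle.dumps(
        (model.forest_.model_, model.encoder_.encoded_columns_), protocol=4
    )
    return hashlib.sha256(payload).hexdigest()


def _fold_metrics(model, train, test, outcome, horizons, early_recurrence):
    """Metrics for one fitted model on one held-out fold."""
    t_tr, e_tr = train.outcome_arrays(outcome)
    t_te, e_te = test.outcome_arrays(outcome)
    rows = []
    eval_points = list(horizons)
    if early_recurrence and outcome == "pfs":
        eval_points.append(EARLY_RECURRENCE_CUTOFF)
    surv = model.predict_survival(test, np.asarray(eval_points, float))
    for j, horizon in enumerate(eval_points):
        label = (
            "early_recurrence"
            if early_recurrence and outcome == "pfs"
            and horizon == EARLY_RECURRENCE_CUTOFF and horizon not in horizons
            else outcome
        )
        try:
            w = censoring_weights(
                t_te, e_te, horizon, fit_times=t_tr, fit_events=e_tr
            )
            auc = time_dependent_auc(1 - surv[:, j], t_te, e_te, horizon, weights=w)
            bs = brier_score(surv[:, j], t_te, e_te, horizon, weights=w)
        except UndefinedMetricError:
            auc, bs = np.nan, np.nan
        rows.append((label, horizon, "AUC", auc))
        rows.append((label, horizon, "Brier", bs))
    return rows


def repeated_cv(
    cohort: Cohort,
    variants=("A", "B", "C"),
    outcome: str = "pfs",
    horizons=DEFAULT_HORIZONS,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    estimator_params: dict | None = None,
    early_recurrence: bool = False,
    folds=None,
    return_models: bool = False,
):
    """Repeated stratified k-fold CV of the model variants.

    Returns a MetricTable DataFrame (one row per variant x outcome x horizon x
    metric, estimates averaged over all folds and repeats) whose ``attrs``
    carry the replication metadata. With ``return_models=True`` also returns a
    dict of per-fold model fingerprints for reproducibility audits.
    """
    params = dict(estimator_params or {})
    if folds is None:
        folds = make_folds(cohort, outcome, k, repeats, seed)
    records = []
    fingerprints = {}
    for r, fold_list in enumerate(folds):
        for f, (train_ids, test_ids) in enumerate(fold_list):
            train = cohort.subset(train_ids)
            test = cohort.subset(test_ids)
            _, ev = train.outcome_arrays(outcome)
            if not ev.any():
                raise UndefinedMetricError(
                    f"repeat {r} fold {f}: training fold has zero events"
                )
            for variant in variants:
                model = FunctionalSurvivalForest(
                    variant=variant,
                    outcome=outcome,
                    random_state=seed + 7919 * r + 104729 * f,
                    **params,
                ).fit(train)
                if return_models:
                    fingerprints[(r, f, variant)] = _model_fingerprint(model)
                for label, horizon, metric, value in _fold_metrics(
                    model, train, test, outcome, horizons, early_recurrence
                ):
                    records.append(
                        {
                            "model": variant,
                            "outcome": label,
                            "horizon": horizon,
                            "metric": metric,
                            "value": value,
                            "repeat": r,
                            "fold": f,
                        }
                    )
    raw = pd.DataFrame(records)
    table = (
        raw.groupby(["model", "outcome", "horizon", "metric"], as_index=False)
        .agg(estimate=("value", "mean"), n_folds=("value", "size"))
    )
    table.attrs.update(
        {"k": k, "repeats": len(folds), "seed": seed, "outcome": outcome}
    )
    if return_models:
        return table, raw, fingerprints
    return table, raw


def external_validation(
    models: dict,
    external_cohort: Cohort,
    outcome: str = "pfs",
    horizons=DEFAULT_HORIZONS,
    n_bootstrap: int = 1000,
    seed: int = 0,
    early_recurrence: bool = False,
) -> pd.DataFrame:
    """Evaluate fitted models on an external cohort with bootstrap 95% CIs.

    ``models`` maps variant label to a fitted FunctionalSurvivalForest trained
    on a separate cohort. Censoring weights use the external cohort itself.
    Percentile CIs from ``n_bootstrap`` subject-level resamples.
    """
    times, events = external_cohort.outcome_arrays(outcome)
    n = len(external_cohort)
    rng = np.random.default_rng(seed)
    eval_points = list(horizons)
    labels = [outcome] * len(horizons)
    if early_recurrence and outcome == "pfs":
        eval_points.append(EARLY_RECURRENCE_CUTOFF)
        labels.append("early_recurrence")
    rows = []
    boot_idx = rng.integers(0, n, size=(n_bootstrap, n)) if n_bootstrap > 1 else None
    for variant, model in models.items():
        surv = model.predict_survival(external_cohort, np.asarray(eval_points))
        for j, (horizon, label) in enumerate(zip(eval_points, labels)):
            def compute(idx):
                t, e, s = times[idx], events[idx], surv[idx, j]
                w = censoring_weights(t, e, horizon)
                return (
                    time_dependent_auc(1 - s, t, e, horizon, weights=w),
                    brier_score(s, t, e, horizon, weights=w),
                )

            auc, bs = compute(np.arange(n))
            cis = {"AUC": (np.nan, np.nan), "Brier": (np.nan, np.nan)}
            if boot_idx is not None:
                boots = []
                for idx in boot_idx:
                    try:
                        boots.append(compute(idx))
                    except UndefinedMetricError:
                        continue
                if boots:
                    arr = np.array(boots)
                    cis["AUC"] = tuple(np.percentile(arr[:, 0], [2.5, 97.5]))
                    cis["Brier"] = tuple(np.percentile(arr[:, 1], [2.5, 97.5]))
            for metric, value in (("AUC", auc), ("Brier", bs)):
                rows.append(
                    {
                        "model": variant,
                        "outcome": label,
                        "horizon": horizon,
                        "metric": metric,
                        "estimate": value,
                        "ci_lower": cis[metric][0],
                        "ci_upper": cis[metric][1],
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs.update({"n_bootstrap": n_bootstrap, "seed": seed})
    return table
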