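"""Right-censoring-aware performance metrics.

Discrimination is the cumulative-cases / dynamic-controls time-dependent AUC
and accuracy the Brier score, both corrected for censoring by inverse
probability of censoring weighting (IPCW): cases observed by the horizon are
weighted by 1/G(T-), subjects still at risk at the horizon by 1/G(t), where G
is the Kaplan-Meier estimate of the censoring distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


class UndefinedMetricError(RuntimeError):
    """The metric is undefined for this data/horizon combination."""


def censoring_survival(times, events):
    """Kaplan-Meier of the censoring distribution G.

    Censoring (event == 0) is the 'event'; returns (jump_times, g_values) of
    the right-continuous step function with G(0) = 1.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    order = np.argsort(times)
    t_sorted = times[order]
    cens_sorted = ~events[order]
    uniq = np.unique(t_sorted)
    n = times.size
    g = 1.0
    g_vals = np.empty(uniq.size)
    at_risk = n
    start = 0
    for i, u in enumerate(uniq):
        block = np.searchsorted(t_sorted, u, side="right") - start
        d_c = int(cens_sorted[start : start + block].sum())
        if at_risk > 0 and d_c > 0:
            g *= 1.0 - d_c / at_risk
        g_vals[i] = g
        at_risk -= block
        start += block
    return uniq, g_vals


def _step_eval(jump_times, values, t, left_limit=False):
    """Evaluate a right-continuous step function starting at 1 before jumps."""
    t = np.asarray(t, float)
    side = "left" if left_limit else "right"
    idx = np.searchsorted(jump_times, t, side=side) - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, None)], 1.0)
    return out


def censoring_weights(times, events, horizon, fit_times=None, fit_events=None):
    """IPCW weights at an evaluation horizon.

    Events before the horizon get 1/G(T-); subjects at risk past the horizon
    get 1/G(horizon); censored-before-horizon subjects get 0. G may be
    estimated on a different sample (``fit_times``/``fit_events``), e.g. the
    training fold.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    gt, gv = censoring_survival(
        times if fit_times is None else fit_times,
        events if fit_events is None else fit_events,
    )
    w = np.zeros(times.size)
    is_case = (times <= horizon) & events
    at_risk = times > horizon
    g_case = _step_eval(gt, gv, times[is_case], left_limit=True)
    g_horiz = float(_step_eval(gt, gv, np.array([horizon]))[0])
    if (g_case <= 0).any() or (at_risk.any() and g_horiz <= 0):
        raise UndefinedMetricError(
            f"censoring survival reaches 0 before horizon {horizon}; "
            "reduce the evaluation horizon"
        )
    if not (is_case.any() or at_risk.any()):
        raise UndefinedMetricError(
            f"no usable subjects at horizon {horizon} (all censored earlier)"
        )
    w[is_case] = 1.0 / g_case
    if at_risk.any():
        w[at_risk] = 1.0 / g_horiz
    return w


def time_dependent_auc(risk_scores, times, events, horizon, weights=None):
    """IPCW cumulative/dynamic AUC at one horizon.

    ``risk_scores`` is the predicted event probability by the horizon (any
    monotone transform gives the same value). Cases are subjects with an
    observed event by the horizon, controls those still at risk; tied risk
    scores count 1/2.
    """
    risk = np.asarray(risk_scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if weights is None:
        weights = censoring_weights(times, events, horizon)
    w = np.asarray(weights, float)
    cases = (times <= horizon) & events & (w > 0)
    controls = (times > horizon) & (w > 0)
    if not cases.any() or not controls.any():
        raise UndefinedMetricError(
            f"AUC undefined at horizon {horizon}: "
            f"{int(cases.sum())} cases, {int(controls.sum())} controls"
        )
    r_case, w_case = risk[cases], w[cases]
    r_ctrl, w_ctrl = risk[controls], w[controls]
    diff = r_case[:, None] - r_ctrl[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    pair_w = w_case[:, None] * w_ctrl[None, :]
    return float((conc * pair_w).sum() / pair_w.sum())


def brier_score(predicted_survival, times, events, horizon, weights=None):
    """IPCW Brier score at one horizon.

    ``predicted_survival`` is S(horizon) per subject. Without censoring this
    reduces to the plain mean squared error between the event indicator and
    the predicted event probability.
    """
    surv = np.asarray(predicted_survival, float)
    if ((surv < -1e-9) | (surv > 1 + 1e-9)).any():
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if weights is None:
        weights = censoring_weights(times, events, horizon)
    w = np.asarray(weights, float)
    is_case = (times <= horizon) & events
    resid = np.where(is_case, surv**2, (1.0 - surv) ** 2)
    return float(np.mean(w * resid))


def early_recurrence_metrics(model, cohort, cutoff: float = 13.0):
    """AUC and Brier for the binary early-recurrence endpoint.

    Early recurrence is progression within ``cutoff`` months (13 by default);
    the risk is the PFS model's 1 - S(cutoff), evaluated with the same IPCW
    machinery at horizon = cutoff.
    """
    times, events = cohort.outcome_arrays("pfs")
    surv = model.predict_survival(cohort, np.array([cutoff]))[:, 0]
    w = censoring_weights(times, events, cutoff)
    auc = time_dependent_auc(1.0 - surv, times, events, cutoff, weights=w)
    bs = brier_score(surv, times, events, cutoff, weights=w)
    return auc, bs


def calibration_table(
    predicted_event_prob, times, events, horizon, n_groups: int = 5
) -> pd.DataFrame:
    """Predicted vs Kaplan-Meier-observed event probability by risk quantile.

    Returns one row per bin: n, mean predicted probability, observed event
    probability at the horizon with its Greenwood 95% CI.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    pred = np.asarray(predicted_event_prob, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    bins = pd.qcut(pred, q=n_groups, duplicates="drop")
    if len(bins.categories) == 0:  # constant predictions: one effective bin
        labels, masks = ["all"], [np.ones(pred.size, dtype=bool)]
    else:
        labels = [str(c) for c in bins.categories]
        masks = [np.asarray(bins == c) for c in bins.categories]
    rows = []
    for label, mask in zip(labels, masks):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        s_obs = float(kmf.predict(horizon))
        ci = kmf.confidence_interval_survival_function_
        idx = ci.index.searchsorted(horizon, side="right") - 1
        if idx >= 0:
            lower_s, upper_s = ci.iloc[idx].to_numpy()
        else:
            lower_s, upper_s = 1.0, 1.0
        rows.append(
            {
                "bin": str(label),
                "n": int(mask.sum()),
                "mean_predicted": float(pred[mask].mean()),
                "observed": 1.0 - s_obs,
                "observed_ci_lower": 1.0 - upper_s,
                "observed_ci_upper": 1.0 - lower_s,
            }
        )
    return pd.DataFrame(rows)
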