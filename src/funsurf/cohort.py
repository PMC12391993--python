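"""Cohort containers and plumbing: subject records, eligibility, CSV round-trips.

A cohort holds, per subject, the baseline clinicopathologic covariates, the
longitudinal analysis-marker measurements (time in months from surgery, with
the preoperative draw mapped to t=0), and the two right-censored outcomes
(progression-free and overall survival). Eligibility mirrors a surgical-cohort
enrolment flow: subjects need a preoperative measurement and at least two
postoperative measurements within the first 12 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import ANALYSIS_MARKERS

#: Baseline clinicopathologic covariates (18), as collected in a typical
#: resected colorectal-liver-metastasis cohort. Age, metastasis count and
#: diameter are continuous; everything else is a 0/1 indicator.
BASELINE_COVARIATES = (
    "age",
    "male_sex",
    "comorbidity",
    "asa_1_2",
    "preop_chemotherapy",
    "primary_colon",
    "right_hemicolon",
    "bilobar_distribution",
    "n_liver_metastases",
    "diameter_liver_metastases_cm",
    "extrahepatic_metastases",
    "major_liver_resection",
    "r0_resection",
    "poor_differentiation",
    "t3_t4_stage",
    "n1_n2_stage",
    "kras_mutation",
    "adjuvant_chemotherapy",
)

#: Measurement-time window in months from surgery: the preoperative draw
#: (within one week before surgery) carries a small negative offset before it
#: is mapped to 0; postoperative follow-up is windowed to 12 months.
TIME_WINDOW = (-0.25, 12.0)


class SchemaError(ValueError):
    """An input table violates the documented schema."""


@dataclass
class SubjectRecord:
    """One patient: baseline covariates, marker history, outcomes."""

    subject_id: str
    baseline: dict
    measurements: pd.DataFrame  # columns: marker, time_months, value
    pfs_time_months: float
    pfs_event: bool
    os_time_months: float
    os_event: bool

    def marker_observations(self, marker: str, up_to: float | None = None):
        """(times, values) for one marker, optionally truncated at a landmark."""
        sub = self.measurements[self.measurements["marker"] == marker]
        if up_to is not None:
            sub = sub[sub["time_months"] <= up_to]
        sub = sub.sort_values("time_months")
        return sub["time_months"].to_numpy(float), sub["value"].to_numpy(float)


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    marker_names: tuple[str, ...] = ANALYSIS_MARKERS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate subject ids in cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subset(self, ids) -> "Cohort":
        wanted = set(ids)
        return Cohort(
            [s for s in self.subjects if s.subject_id in wanted],
            self.marker_names,
            dict(self.provenance),
        )

    def longitudinal_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:
            f = s.measurements.copy()
            f.insert(0, "subject_id", s.subject_id)
            frames.append(f)
        if not frames:
            return pd.DataFrame(
                columns=["subject_id", "marker", "time_months", "value"]
            )
        return pd.concat(frames, ignore_index=True)

    def baseline_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id}
            row.update(s.baseline)
            rows.append(row)
        return pd.DataFrame(rows)

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids(),
                "pfs_time_months": [s.pfs_time_months for s in self.subjects],
                "pfs_event": [int(s.pfs_event) for s in self.subjects],
                "os_time_months": [s.os_time_months for s in self.subjects],
                "os_event": [int(s.os_event) for s in self.subjects],
            }
        )

    def outcome_arrays(self, outcome: str):
        """(times, events) for ``outcome`` in {'pfs', 'os'}."""
        if outcome not in ("pfs", "os"):
            raise ValueError(f"outcome must be 'pfs' or 'os', got {outcome!r}")
        times = np.array([getattr(s, f"{outcome}_time_months") for s in self.subjects])
        events = np.array(
            [getattr(s, f"{outcome}_event") for s in self.subjects], dtype=bool
        )
        return times, events


def _check_measurements(meas: pd.DataFrame, subject_id: str) -> pd.DataFrame:
    dup = meas.duplicated(subset=["marker", "time_months"])
    if dup.any():
        row = meas[dup].iloc[0]
        raise SchemaError(
            f"duplicate measurement for subject {subject_id}, marker "
            f"{row['marker']} at t={row['time_months']}"
        )
    if not np.isfinite(meas["value"].to_numpy(float)).all():
        raise SchemaError(f"non-finite measurement value for subject {subject_id}")
    lo, hi = TIME_WINDOW
    t = meas["time_months"].to_numpy(float)
    if ((t < lo) | (t > hi)).any():
        raise SchemaError(
            f"measurement time outside [{lo}, {hi}] months for subject {subject_id}"
        )
    # preoperative draws (t < 0, within one week before surgery) map to t = 0
    meas = meas.copy()
    meas.loc[meas["time_months"] < 0, "time_months"] = 0.0
    return meas.sort_values(["marker", "time_months"]).reset_index(drop=True)


def assemble_cohort(
    longitudinal: pd.DataFrame,
    baseline: pd.DataFrame,
    outcomes: pd.DataFrame,
    marker_names=None,
    provenance: dict | None = None,
) -> Cohort:
    """Build a Cohort from the three long/wide tables (schema-checked)."""
    for name, frame, cols in (
        ("longitudinal", longitudinal, ["subject_id", "marker", "time_months", "value"]),
        ("baseline", baseline, ["subject_id"]),
        ("outcomes", outcomes, ["subject_id", "pfs_time_months", "pfs_event",
                                "os_time_months", "os_event"]),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise SchemaError(f"{name} table missing columns: {sorted(missing)}")
    if marker_names is None:  # infer the panel from the data
        marker_names = tuple(sorted(longitudinal["marker"].unique()))
    unknown = set(longitudinal["marker"]) - set(marker_names)
    if unknown:
        raise SchemaError(f"unknown marker names: {sorted(unknown)}")
    if baseline["subject_id"].duplicated().any():
        raise SchemaError("duplicate subject_id in baseline table")
    if outcomes["subject_id"].duplicated().any():
        raise SchemaError("duplicate subject_id in outcomes table")

    baseline = baseline.set_index("subject_id")
    outcomes = outcomes.set_index("subject_id")
    subjects = []
    for sid, grp in longitudinal.groupby("subject_id", sort=True):
        if sid not in outcomes.index:
            raise SchemaError(f"subject {sid} has measurements but no outcome row")
        out = outcomes.loc[sid]
        for col in ("pfs_time_months", "os_time_months"):
            if not out[col] > 0:
                raise SchemaError(f"subject {sid}: {col} must be positive")
        if (
            bool(out["pfs_event"])
            and bool(out["os_event"])
            and out["pfs_time_months"] > out["os_time_months"] + 1e-9
        ):
            raise SchemaError(f"subject {sid}: PFS time exceeds OS time")
        meas = _check_measurements(
            grp[["marker", "time_months", "value"]].reset_index(drop=True), sid
        )
        base = (
            baseline.loc[sid].to_dict() if sid in baseline.index else {}
        )
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                baseline=base,
                measurements=meas,
                pfs_time_months=float(out["pfs_time_months"]),
                pfs_event=bool(out["pfs_event"]),
                os_time_months=float(out["os_time_months"]),
                os_event=bool(out["os_event"]),
            )
        )
    return Cohort(subjects, tuple(marker_names), provenance or {})


def apply_eligibility_filters(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
    """Enrolment filters: preoperative draw present, >=2 postoperative
    measurements in (0, 12], positive follow-up.

    Returns the retained cohort and an exclusion log (subject_id, rule).
    """
    retained: list[SubjectRecord] = []
    log: list[tuple[str, str]] = []
    for s in cohort.subjects:
        t = s.measurements["time_months"].to_numpy(float)
        if s.pfs_time_months <= 0 or s.os_time_months <= 0:
            log.append((s.subject_id, "zero follow-up"))
        elif not (t == 0).any():
            log.append((s.subject_id, "no preoperative measurement"))
        elif np.unique(t[(t > 0) & (t <= 12)]).size < 2:
            log.append((s.subject_id, "<2 postoperative measurements"))
        else:
            retained.append(s)
    exclusions = pd.DataFrame(log, columns=["subject_id", "rule"])
    return Cohort(retained, cohort.marker_names, dict(cohort.provenance)), exclusions


def _read_csv(path, required, name):
    frame = pd.read_csv(path)
    missing = set(required) - set(frame.columns)
    if missing:
        raise SchemaError(f"{name} file {path}: missing columns {sorted(missing)}")
    return frame


def read_cohort(
    longitudinal_path, baseline_path, outcomes_path, marker_names=None
) -> Cohort:
    """Read a cohort from the three CSV files (see module docs for schemas)."""
    longitudinal = _read_csv(
        longitudinal_path, ["subject_id", "marker", "time_months", "value"],
        "longitudinal",
    )
    if not pd.api.types.is_numeric_dtype(longitudinal["value"]):
        bad = longitudinal[pd.to_numeric(longitudinal["value"], errors="coerce").isna()]
        raise SchemaError(
            f"non-numeric value in longitudinal file, first bad row index "
            f"{bad.index[0] if len(bad) else '?'}"
        )
    longitudinal["subject_id"] = longitudinal["subject_id"].astype(str)
    baseline = _read_csv(baseline_path, ["subject_id"], "baseline")
    baseline["subject_id"] = baseline["subject_id"].astype(str)
    outcomes = _read_csv(
        outcomes_path,
        ["subject_id", "pfs_time_months", "pfs_event", "os_time_months", "os_event"],
        "outcomes",
    )
    outcomes["subject_id"] = outcomes["subject_id"].astype(str)
    return assemble_cohort(longitudinal, baseline, outcomes, marker_names,
                           provenance={"source": str(longitudinal_path)})


def write_cohort(cohort: Cohort, longitudinal_path, baseline_path, outcomes_path):
    """Write the three cohort CSVs (UTF-8, '.' decimal, header row)."""
    cohort.longitudinal_frame().to_csv(longitudinal_path, index=False)
    cohort.baseline_frame().to_csv(baseline_path, index=False)
    cohort.outcomes_frame().to_csv(outcomes_path, index=False)
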