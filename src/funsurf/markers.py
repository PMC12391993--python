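"""Derivation of the 9 analysis markers from 11 routine hematological measurements.

Five markers pass through directly (CEA, CA19-9, GGT, RDW-SD, RDW-CV); four are
composites of liver-function and blood-count labs: APRI and FIB-4 and the
S-index (liver-fibrosis indices) and the neutrophil-to-lymphocyte ratio (NLR).
Composites are computed per visit and only when every constituent is present at
that visit; a missing constituent yields an absent record, never an imputation.
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd

RAW_MARKERS = (
    "CEA",
    "CA19-9",
    "RDW-SD",
    "RDW-CV",
    "neutrophil",
    "lymphocyte",
    "platelet",
    "GGT",
    "AST",
    "ALT",
    "ALB",
)

#: The nine analysis markers carried into the longitudinal model.
ANALYSIS_MARKERS = (
    "CEA",
    "CA19-9",
    "GGT",
    "RDW-SD",
    "RDW-CV",
    "APRI",
    "FIB-4",
    "S-index",
    "NLR",
)

_PASSTHROUGH = ("CEA", "CA19-9", "GGT", "RDW-SD", "RDW-CV")

#: Default upper limit of normal for AST, in U/L. Assay-dependent; must be
#: supplied explicitly when the local laboratory uses a different limit.
DEFAULT_AST_ULN = 40.0


class MarkerDomainError(ValueError):
    """A composite-marker constituent is outside its valid domain."""


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value) or value <= 0:
            raise MarkerDomainError(
                f"{name} must be a positive finite number, got {value!r}"
            )


def compute_apri(ast: float, ast_uln: float, platelets: float) -> float:
    """AST-to-platelet ratio index: ``100 * (ast / ast_uln) / platelets``.

    Parameters
    ----------
    ast : AST in U/L.
    ast_uln : upper limit of normal for AST in U/L.
    platelets : platelet count in 10^9/L.
    """
    _require_positive(ast=ast, ast_uln=ast_uln, platelets=platelets)
    return 100.0 * (ast / ast_uln) / platelets


def compute_fib4(age: float, ast: float, alt: float, platelets: float) -> float:
    """FIB-4 index: ``age * ast / (platelets * sqrt(alt))``.

    Age in years, AST/ALT in U/L, platelets in 10^9/L.
    """
    _require_positive(age=age, ast=ast, alt=alt, platelets=platelets)
    return age * ast / (platelets * math.sqrt(alt))


def compute_s_index(ggt: float, platelets: float, albumin: float) -> float:
    """S-index: ``1000 * ggt / (platelets * albumin**2)``.

    GGT in U/L, platelets in 10^9/L, albumin in g/L. With albumin around
    40 g/L and platelets around 200, typical values sit near 0.1.
    """
    _require_positive(ggt=ggt, platelets=platelets, albumin=albumin)
    return 1000.0 * ggt / (platelets * albumin**2)


def compute_nlr(neutrophils: float, lymphocytes: float) -> float:
    """Neutrophil-to-lymphocyte ratio (both counts in 10^9/L)."""
    _require_positive(neutrophils=neutrophils, lymphocytes=lymphocytes)
    return neutrophils / lymphocytes


def derive_marker_panel(
    raw: pd.DataFrame,
    age: float | pd.Series,
    ast_uln: float = DEFAULT_AST_ULN,
) -> pd.DataFrame:
    """Derive the 9 analysis markers from long-format raw measurements.

    Parameters
    ----------
    raw : DataFrame with columns ``subject_id, marker, time_months, value``;
        marker names must come from :data:`RAW_MARKERS`.
    age : age in years, either a scalar (single-subject input) or a Series
        indexed by subject id (needed for FIB-4).
    ast_uln : AST upper limit of normal in U/L.

    Returns
    -------
    DataFrame in the same long format holding only analysis-marker records.
    Composite markers are emitted only at visits where every constituent is
    present; otherwise that composite is simply absent at that visit.
    """
    required = {"subject_id", "marker", "time_months", "value"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise ValueError(f"raw table missing columns: {sorted(missing_cols)}")
    unknown = set(raw["marker"]) - set(RAW_MARKERS)
    if unknown:
        raise ValueError(f"unknown raw marker names: {sorted(unknown)}")
    if raw.empty:
        return raw.iloc[0:0].copy()

    if isinstance(age, pd.Series):
        age_of = age.to_dict()
    else:
        age_of = None

    # one row per visit, one column per raw marker
    wide = raw.pivot_table(
        index=["subject_id", "time_months"],
        columns="marker",
        values="value",
        aggfunc="first",
    )

    records: list[tuple] = []

    def emit(sid, t, name, value):
        records.append((sid, name, t, float(value)))

    for (sid, t), row in wide.iterrows():
        for name in _PASSTHROUGH:
            if name in row.index and pd.notna(row.get(name)):
                emit(sid, t, name, row[name])
        subj_age = age_of[sid] if age_of is not None else age
        plt_ = row.get("platelet")
        ast_ = row.get("AST")
        alt_ = row.get("ALT")
        alb_ = row.get("ALB")
        ggt_ = row.get("GGT")
        neut = row.get("neutrophil")
        lymph = row.get("lymphocyte")
        if pd.notna(plt_) and pd.notna(ast_):
            emit(sid, t, "APRI", compute_apri(ast_, ast_uln, plt_))
        if pd.notna(plt_) and pd.notna(ast_) and pd.notna(alt_) and pd.notna(subj_age):
            emit(sid, t, "FIB-4", compute_fib4(subj_age, ast_, alt_, plt_))
        if pd.notna(ggt_) and pd.notna(plt_) and pd.notna(alb_):
            emit(sid, t, "S-index", compute_s_index(ggt_, plt_, alb_))
        if pd.notna(neut) and pd.notna(lymph):
            emit(sid, t, "NLR", compute_nlr(neut, lymph))

    out = pd.DataFrame(
        records, columns=["subject_id", "marker", "time_months", "value"]
    )
    return out.sort_values(["subject_id", "time_months", "marker"]).reset_index(
        drop=True
    )


def marker_transform_rules(markers: Iterable[str]) -> dict[str, str]:
    """Default per-marker pre-transform for FPCA.

    Right-skewed markers (tumor markers, liver enzymes, fibrosis indices, NLR)
    get ``log1p-z`` (log1p then z-standardization); the RDW dispersion measures
    and any unrecognized (e.g. synthetic) marker get plain ``z``.
    """
    skewed = {"CEA", "CA19-9", "GGT", "APRI", "FIB-4", "S-index", "NLR"}
    return {m: ("log1p-z" if m in skewed else "z") for m in markers}
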