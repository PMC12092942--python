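"""Assessment-table data model: reading, validation, pre-processing, descriptives.

An *assessment* is one Neurostatus-EDSS visit: 100 mandatory subscore grades,
their P/T labels (deficits marked Permanent or Temporary and not MS-related),
7 Functional System Scores, the Ambulation Score and the EDSS, plus
demographics.  Tables are plain pandas DataFrames in the documented CSV
schema; every public function takes and returns such frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import EDSS_GRID, FS_NAMES, SubscoreCatalog

META_COLUMNS = ["patient_id", "visit_index", "visit_month", "age", "sex",
                "edss", "ambulation_score"]

#: Reserved prefix for generator ground-truth columns; analysis stages must
#: never read these.
TRUTH_PREFIX = "truth_"


class SchemaError(ValueError):
    """The table is structurally wrong (missing/unknown columns)."""


class ValidationError(ValueError):
    """Rows violate value-level invariants; message lists row diagnostics."""


def fss_column(fs: str) -> str:
    return f"fss_{fs}"


def subscore_column(subscore_id: str) -> str:
    return f"ss_{subscore_id}"


def pt_column(subscore_id: str) -> str:
    return f"pt_{subscore_id}"


def schema_columns(catalog: SubscoreCatalog) -> list[str]:
    """Canonical column order of the assessment CSV."""
    return (META_COLUMNS
            + [fss_column(fs) for fs in FS_NAMES]
            + [subscore_column(i) for i in catalog.ids]
            + [pt_column(i) for i in catalog.ids])


def validate_assessments(table: pd.DataFrame, catalog: SubscoreCatalog,
                         strict: bool = True) -> tuple[pd.DataFrame, list[str]]:
    """Check value-level invariants; return (valid rows, diagnostics).

    With ``strict=True`` any violation raises :class:`ValidationError`
    carrying all row-level diagnostics; otherwise offending rows are dropped
    and reported.
    """
    missing = [c for c in schema_columns(catalog) if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing[:8]}"
                          + ("..." if len(missing) > 8 else ""))

    bad = pd.Series(False, index=table.index)
    diagnostics: list[str] = []

    edss_ok = table["edss"].isin(EDSS_GRID)
    for idx in table.index[~edss_ok]:
        diagnostics.append(f"row {idx}: edss {table.at[idx, 'edss']} not on the "
                           "0.0-10.0 half-point grid")
    bad |= ~edss_ok

    for sid in catalog.ids:
        s = catalog[sid]
        col = table[subscore_column(sid)]
        ok = col.between(s.lo, s.hi) & (col == col.round())
        for idx in table.index[~ok]:
            diagnostics.append(f"row {idx}: subscore {sid} grade {col.at[idx]} "
                               f"outside legal range [{s.lo}, {s.hi}]")
        bad |= ~ok
        labels = table[pt_column(sid)].fillna("")
        lab_ok = labels.isin(["", "P", "T"])
        for idx in table.index[~lab_ok]:
            diagnostics.append(f"row {idx}: pt label {labels.at[idx]!r} for {sid} "
                               "not in {'', 'P', 'T'}")
        bad |= ~lab_ok

    if strict and diagnostics:
        raise ValidationError(f"{int(bad.sum())} invalid rows:\n"
                              + "\n".join(diagnostics[:20]))
    return table.loc[~bad].copy(), diagnostics


def read_assessments(path, catalog: SubscoreCatalog,
                     strict: bool = True) -> pd.DataFrame:
    """Read and validate an assessment CSV (see :func:`schema_columns`)."""
    table = pd.read_csv(path, dtype={"patient_id": str},
                        keep_default_na=False, na_values=[])
    for sid in catalog.ids:
        table[pt_column(sid)] = table[pt_column(sid)].astype(str)
    valid, _ = validate_assessments(table, catalog, strict=strict)
    return valid


def write_assessments(table: pd.DataFrame, path, catalog: SubscoreCatalog) -> None:
    cols = schema_columns(catalog)
    extra = [c for c in table.columns if c.startswith(TRUTH_PREFIX)]
    table[cols + extra].to_csv(path, index=False)


def adjust_pt_labels(table: pd.DataFrame, catalog: SubscoreCatalog) -> pd.DataFrame:
    """Replace every P/T-labelled grade by the subscore's normal value.

    Deficits flagged as permanent or temporary and *not* MS-related are
    neutralized before any analysis; labels are retained for audit.
    Idempotent.
    """
    out = table.copy()
    for sid in catalog.ids:
        labelled = out[pt_column(sid)].isin(["P", "T"])
        if labelled.any():
            out.loc[labelled, subscore_column(sid)] = catalog[sid].normal
    return out


@dataclass
class DescriptiveSummary:
    n_assessments: int
    n_patients: int
    visits_mean: float
    visits_sd: float
    pct_edss_4_to_6_5: float
    modal_edss: float
    edss_histogram: dict = field(default_factory=dict)   # edss -> count
    fss_by_edss: dict = field(default_factory=dict)      # edss -> fs -> 5-number
    age_mean: float = math.nan
    age_sd: float = math.nan
    pct_female: float = math.nan

    def to_dict(self) -> dict:
        return {
            "n_assessments": self.n_assessments,
            "n_patients": self.n_patients,
            "visits_mean": self.visits_mean,
            "visits_sd": self.visits_sd,
            "pct_edss_4_to_6_5": self.pct_edss_4_to_6_5,
            "modal_edss": self.modal_edss,
            "edss_histogram": {str(k): v for k, v in self.edss_histogram.items()},
            "fss_by_edss": {str(k): v for k, v in self.fss_by_edss.items()},
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "pct_female": self.pct_female,
        }


def describe(table: pd.DataFrame) -> DescriptiveSummary:
    """Cohort descriptives: EDSS histogram, per-EDSS FSS five-number summaries."""
    if len(table) == 0:
        raise ValueError("empty assessment table")

    hist = table["edss"].value_counts().sort_index()
    per_patient = table.groupby("patient_id")["visit_index"].count()
    in_range = table["edss"].between(4.0, 6.5)

    fss_cols = [fss_column(fs) for fs in FS_NAMES if fss_column(fs) in table.columns]
    fss_by_edss: dict = {}
    for edss, sub in table.groupby("edss"):
        fss_by_edss[float(edss)] = {
            col.removeprefix("fss_"): {
                "min": float(sub[col].min()),
                "q1": float(sub[col].quantile(0.25)),
                "median": float(sub[col].median()),
                "q3": float(sub[col].quantile(0.75)),
                "max": float(sub[col].max()),
            }
            for col in fss_cols
        }

    ages = table.groupby("patient_id")["age"].first()
    sexes = table.groupby("patient_id")["sex"].first()
    return DescriptiveSummary(
        n_assessments=len(table),
        n_patients=table["patient_id"].nunique(),
        visits_mean=float(per_patient.mean()),
        visits_sd=float(per_patient.std(ddof=1)) if len(per_patient) > 1 else 0.0,
        pct_edss_4_to_6_5=float(100.0 * in_range.mean()),
        modal_edss=float(hist.idxmax()),
        edss_histogram={float(k): int(v) for k, v in hist.items()},
        fss_by_edss=fss_by_edss,
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
        pct_female=float(100.0 * (sexes == "female").mean()),
    )


def required_cdw_increase(baseline_edss: float, zero_baseline_increase: float = 1.5) -> float:
    """Minimum EDSS increase over baseline that counts as worsening.

    Standard definition: +1.0 for baselines 1.0-5.0 and +0.5 for baselines
    5.5 and above.  A baseline of 0 conventionally requires +1.5 (the note
    defining CDW does not cover it); baselines of 0.5 are treated with the
    1.0-5.0 band.
    """
    if baseline_edss == 0.0:
        return zero_baseline_increase
    if baseline_edss <= 5.0:
        return 1.0
    return 0.5


def compute_cdw(table: pd.DataFrame, confirmation_months: int = 6,
                zero_baseline_increase: float = 1.5) -> pd.Series:
    """Per-patient confirmed-disability-worsening flag.

    A patient is flagged if some visit reaches baseline + required increase
    AND a visit at least ``confirmation_months`` later still does.  A
    worsening at the final visit is unconfirmed and does not flag.
    """
    flags: dict[str, bool] = {}
    missing_baseline = []
    for pid, sub in table.groupby("patient_id", sort=True):
        sub = sub.sort_values("visit_month")
        base_rows = sub[sub["visit_index"] == 0]
        if len(base_rows) == 0:
            missing_baseline.append(pid)
            continue
        baseline = float(base_rows["edss"].iloc[0])
        need = baseline + required_cdw_increase(baseline, zero_baseline_increase)
        months = sub["visit_month"].to_numpy(dtype=float)
        worse = sub["edss"].to_numpy(dtype=float) >= need
        worse_months = months[worse]
        flags[pid] = any((worse_months >= m + confirmation_months).any()
                         for m in worse_months)
    if missing_baseline:
        raise ValidationError(f"patients without baseline visit: {missing_baseline}")
    return pd.Series(flags, name="cdw", dtype=bool)
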