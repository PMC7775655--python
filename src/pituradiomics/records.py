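"""Per-case clinical record: outcome, follow-up, and tabular covariates."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

#: covariate vocabularies; categorical codes used throughout the cohort table
HYPOPITUITARISM_LEVELS = ("none", "single", "multiple")
RESECTION_LEVELS = ("GTR", "STR")

#: columns of the cohort table, mirroring the clinical covariate schema
COVARIATE_COLUMNS = [
    "sex_male",
    "age_years",
    "visual_disturbance",
    "headache",
    "sex_hormone_symptoms",
    "incidental",
    "hypopituitarism",
    "hyperprolactinemia",
    "resection",
    "chiasm_decompression",
    "knosp_high_grade",
    "hardy_high_grade",
    "optic_chiasm_compression",
    "third_ventricle_compression",
    "hydrocephalus",
    "giant_tumor",
    "tumor_height_mm",
    "tumor_volume_cm3",
]


@dataclass
class CaseRecord:
    """One patient: event status, time-to-event, lesion dimensions, covariates.

    ``pr_event`` is the progression/recurrence flag; ``time_months`` is time
    to P/R for events and censoring time otherwise. ``baseline_dims_mm`` and
    ``followup_dims_mm`` are per-axis maximum lesion diameters used by the
    >2 mm progression rule. ``svm_score`` is filled in after model fitting.
    """

    case_id: str
    pr_event: bool
    time_months: float
    baseline_dims_mm: tuple[float, float, float]
    followup_dims_mm: tuple[float, float, float]
    covariates: dict = field(default_factory=dict)
    svm_score: float | None = None

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(f"{self.case_id}: time_months must be > 0")
        for dims in (self.baseline_dims_mm, self.followup_dims_mm):
            if any(d <= 0 for d in dims):
                raise ValueError(f"{self.case_id}: lesion dimensions must be positive")
        hp = self.covariates.get("hypopituitarism")
        if hp is not None and hp not in HYPOPITUITARISM_LEVELS:
            raise ValueError(f"{self.case_id}: hypopituitarism {hp!r} not in {HYPOPITUITARISM_LEVELS}")
        rs = self.covariates.get("resection")
        if rs is not None and rs not in RESECTION_LEVELS:
            raise ValueError(f"{self.case_id}: resection {rs!r} not in {RESECTION_LEVELS}")

    def to_row(self) -> dict:
        row = {
            "case_id": self.case_id,
            "pr_event": int(self.pr_event),
            "time_months": self.time_months,
        }
        for ax, name in enumerate(("d1", "d2", "d3")):
            row[f"baseline_{name}_mm"] = self.baseline_dims_mm[ax]
            row[f"followup_{name}_mm"] = self.followup_dims_mm[ax]
        row.update(self.covariates)
        if self.svm_score is not None:
            row["svm_score"] = self.svm_score
        return row


def records_to_frame(records: list[CaseRecord]) -> pd.DataFrame:
    """Cohort table, one row per case."""
    return pd.DataFrame([r.to_row() for r in records]).set_index("case_id")


def frame_to_records(df: pd.DataFrame) -> list[CaseRecord]:
    """Inverse of :func:`records_to_frame` (covariates = all extra columns)."""
    out = []
    dim_cols = [f"{w}_{n}_mm" for w in ("baseline", "followup") for n in ("d1", "d2", "d3")]
    for cid, row in df.iterrows():
        cov = {k: row[k] for k in row.index
               if k not in dim_cols + ["pr_event", "time_months", "svm_score"]}
        out.append(CaseRecord(
            case_id=str(cid),
            pr_event=bool(row["pr_event"]),
            time_months=float(row["time_months"]),
            baseline_dims_mm=tuple(float(row[f"baseline_{n}_mm"]) for n in ("d1", "d2", "d3")),
            followup_dims_mm=tuple(float(row[f"followup_{n}_mm"]) for n in ("d1", "d2", "d3")),
            covariates=cov,
            svm_score=float(row["svm_score"]) if "svm_score" in row.index and pd.notna(row.get("svm_score")) else None,
        ))
    return out
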