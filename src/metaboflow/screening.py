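"""Cohort screening: inclusion/exclusion rules and disposition accounting.

Implements the eligibility rules of a multi-centre case-control plasma
metabolomics cohort: subjects are excluded for age under 18, severe metabolic
disease, pregnancy, unconfirmed diagnosis, emergency treatment, or repeated
enrollment; healthy-group volunteers additionally for diabetes, hypertension,
or cardiovascular disease; and samples for quality failures (visible
hemolysis, discoloration, processing time over 4 h, volume under 60 µL, or
improper storage).  ``screen_subject`` evaluates a single record and returns
every rule that fired; ``disposition`` folds it over a roster and produces the
flow-chart accounting (consenting → excluded per reason → eligible per group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable

__all__ = [
    "SubjectRecord",
    "Disposition",
    "EXCLUSION_REASONS",
    "SAMPLE_QUALITY_REASONS",
    "screen_subject",
    "disposition",
]

#: Canonical tabulation order. A record excluded for several reasons is
#: tabulated under the first one in this list; all reasons are still reported.
EXCLUSION_REASONS = (
    "age_under_18",
    "severe_metabolic_disease",
    "pregnancy",
    "unconfirmed_diagnosis",
    "emergency_treatment",
    "repeat_enrollment",
    "diabetes",
    "hypertension",
    "cardiovascular_disease",
    "hemolysis",
    "discoloration",
    "process_time_over_4h",
    "insufficient_volume",
    "improper_storage",
)

#: Reasons that reflect specimen quality rather than the subject's eligibility.
SAMPLE_QUALITY_REASONS = (
    "hemolysis",
    "discoloration",
    "process_time_over_4h",
    "insufficient_volume",
    "improper_storage",
)

#: Process-time cutoff in minutes ("> 4 h" strictly; 240 itself passes).
PROCESS_TIME_LIMIT_MIN = 240.0
#: Minimum usable plasma volume in µL ("< 60 µL" fails; 60 itself passes).
MIN_VOLUME_UL = 60.0


@dataclass
class SubjectRecord:
    """One consenting subject with demographics and collection-log fields."""

    subject_id: str
    age: float
    group_claimed: str  # cancer | non_cancer | healthy
    diagnosis_confirmed: bool = True
    severe_metabolic_disease: bool = False
    pregnancy: bool = False
    emergency: bool = False
    diabetes: bool = False
    hypertension: bool = False
    cardiovascular: bool = False
    enrollment_count: int = 1
    process_time: float = 60.0  # minutes from draw to -80 °C
    volume: float = 100.0  # µL
    hemolysis: bool = False
    discoloration: bool = False
    improper_storage: bool = False
    # descriptive fields carried through to scheduling; not screened on
    hospital: str = ""
    sex: str = ""
    group: str = ""  # fine-grained group label (e.g. CRC, LC, GC, NC, HCtrl)

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValueError("age must be non-negative")
        if self.volume is not None and self.volume < 0:
            raise ValueError("volume must be non-negative")
        if self.enrollment_count is not None and self.enrollment_count < 1:
            raise ValueError("enrollment_count must be >= 1")


@dataclass
class Disposition:
    """Roster-level screening summary (the patient-flow accounting)."""

    n_consenting: int
    n_excluded: int
    exclusion_counts: dict[str, int]
    n_eligible: int
    group_counts: dict[str, int]
    all_reasons: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_consenting == self.n_excluded + self.n_eligible
        assert sum(self.group_counts.values()) == self.n_eligible


_MANDATORY = (
    "subject_id",
    "age",
    "group_claimed",
    "diagnosis_confirmed",
    "enrollment_count",
    "process_time",
    "volume",
)


def screen_subject(rec: SubjectRecord) -> tuple[bool, list[str]]:
    """Evaluate every exclusion rule on one record.

    Returns ``(eligible, reasons)`` where *reasons* lists all firing rules in
    canonical order (not just the first).  Raises ``ValueError`` naming the
    field if a mandatory field is missing.
    """
    for name in _MANDATORY:
        if getattr(rec, name) is None:
            raise ValueError(f"missing mandatory field: {name}")

    reasons: list[str] = []
    if rec.age < 18:
        reasons.append("age_under_18")
    if rec.severe_metabolic_disease:
        reasons.append("severe_metabolic_disease")
    if rec.pregnancy:
        reasons.append("pregnancy")
    if not rec.diagnosis_confirmed:
        reasons.append("unconfirmed_diagnosis")
    if rec.emergency:
        reasons.append("emergency_treatment")
    if rec.enrollment_count > 1:
        # later enrollments of the same subject are dropped; the first is kept
        reasons.append("repeat_enrollment")
    if rec.group_claimed == "healthy":
        if rec.diabetes:
            reasons.append("diabetes")
        if rec.hypertension:
            reasons.append("hypertension")
        if rec.cardiovascular:
            reasons.append("cardiovascular_disease")
    if rec.hemolysis:
        reasons.append("hemolysis")
    if rec.discoloration:
        reasons.append("discoloration")
    if rec.process_time > PROCESS_TIME_LIMIT_MIN:
        reasons.append("process_time_over_4h")
    if rec.volume < MIN_VOLUME_UL:
        reasons.append("insufficient_volume")
    if rec.improper_storage:
        reasons.append("improper_storage")
    return (len(reasons) == 0, reasons)


def disposition(roster: Iterable[SubjectRecord]) -> Disposition:
    """Fold :func:`screen_subject` over a roster.

    Each excluded subject is tabulated under its first canonical reason;
    the full reason list is kept in ``all_reasons``.  ``group_counts`` is
    computed over eligible subjects only, keyed by the fine-grained ``group``
    label when present, else ``group_claimed``.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("roster is empty")
    exclusion_counts: dict[str, int] = {}
    group_counts: dict[str, int] = {}
    all_reasons: dict[str, list[str]] = {}
    n_excluded = 0
    for rec in roster:
        eligible, reasons = screen_subject(rec)
        if eligible:
            key = rec.group or rec.group_claimed
            group_counts[key] = group_counts.get(key, 0) + 1
        else:
            n_excluded += 1
            all_reasons[rec.subject_id] = reasons
            primary = min(reasons, key=EXCLUSION_REASONS.index)
            exclusion_counts[primary] = exclusion_counts.get(primary, 0) + 1
    return Disposition(
        n_consenting=len(roster),
        n_excluded=n_excluded,
        exclusion_counts=exclusion_counts,
        n_eligible=len(roster) - n_excluded,
        group_counts=group_counts,
        all_reasons=all_reasons,
    )


def roster_to_frame(roster: Iterable[SubjectRecord]):
    """Roster as a DataFrame (one row per subject), for TSV export."""
    import pandas as pd

    cols = [f.name for f in dc_fields(SubjectRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in roster])


def roster_from_frame(df) -> list[SubjectRecord]:
    """Inverse of :func:`roster_to_frame`."""
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["enrollment_count"] = int(d["enrollment_count"])
        out.append(SubjectRecord(**d))
    return out
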