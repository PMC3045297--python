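"""Patient-level domain records, validation and delimited-table I/O.

The analysis operates on three flat tables: one row per enrolled subject
(baseline covariates and disposition), one row per scheduled assessment
(PANSS total and five factor scores, CGI-S, weight), and one row per coded
treatment-emergent adverse event.  Tables are comma-delimited UTF-8 with a
fixed header; absent values are empty cells, never sentinel numbers.  Weeks
are integers with week 0 denoting baseline.

Six short-term placebo-controlled monotherapy trials are modelled: three in
the paliperidone ER program (PALI-SCH-303/304/305, 6-week) and three in the
oral risperidone program (RIS-USA-1 6-week flexible-dose, RIS-INT-3 8-week,
RIS-USA-72 4-week).  The defined analysis groups are paliperidone ER
6-12 mg/day, risperidone 2-4 mg/day, risperidone 4-6 mg/day, and the
program-specific placebo groups.  Subjects with a modal risperidone dose of
exactly 4 mg/day belong to both risperidone dose groups; this dual
membership is exposed through :func:`group_members` as views over a single
underlying subject set, never as duplicated rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

PALI = "PALI"
RIS = "RIS"

PALI_6_12 = "PALI_6_12"
RIS_2_4 = "RIS_2_4"
RIS_4_6 = "RIS_4_6"
PLACEBO_PALI = "PLACEBO_PALI"
PLACEBO_RIS = "PLACEBO_RIS"
EXCLUDED = "EXCLUDED"

TREATMENT_GROUPS = (PALI_6_12, RIS_2_4, RIS_4_6, PLACEBO_PALI, PLACEBO_RIS, EXCLUDED)
ACTIVE_GROUPS = (PALI_6_12, RIS_2_4, RIS_4_6)

PANSS_FACTORS = (
    "negative",
    "positive",
    "anxiety_depression",
    "disorganized_thoughts",
    "hostility_excitement",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class ConfigError(ValueError):
    """An unknown or invalid configuration key was supplied."""


@dataclass(frozen=True)
class TrialMeta:
    """Design constants of one randomized placebo-controlled trial."""

    trial_id: str
    duration_weeks: int
    panss_entry_window: tuple[int, int]
    arms: tuple[tuple[str, tuple[float, float]], ...] = ()
    has_cgi: bool = True
    has_factors: bool = True

    @property
    def endpoint_week(self) -> int:
        # endpoint is the scheduled end of the double-blind phase
        return self.duration_weeks


DEFAULT_TRIALS: dict[str, TrialMeta] = {
    "PALI-SCH-303": TrialMeta("PALI-SCH-303", 6, (70, 120),
                              (("paliperidone ER 6 mg", (6, 6)),
                               ("paliperidone ER 9 mg", (9, 9)),
                               ("paliperidone ER 12 mg", (12, 12)))),
    "PALI-SCH-304": TrialMeta("PALI-SCH-304", 6, (70, 120),
                              (("paliperidone ER 6 mg", (6, 6)),
                               ("paliperidone ER 12 mg", (12, 12)))),
    "PALI-SCH-305": TrialMeta("PALI-SCH-305", 6, (70, 120),
                              (("paliperidone ER 9 mg", (9, 9)),)),
    "RIS-USA-1": TrialMeta("RIS-USA-1", 6, (30, 210),
                           (("risperidone flexible", (1, 10)),),
                           has_factors=False),
    "RIS-INT-3": TrialMeta("RIS-INT-3", 8, (60, 120),
                           (("risperidone 2 mg", (2, 2)),
                            ("risperidone 6 mg", (6, 6)))),
    "RIS-USA-72": TrialMeta("RIS-USA-72", 4, (80, 120),
                            (("risperidone 4 mg", (4, 4)),
                             ("risperidone 8 mg", (8, 8))),
                            has_cgi=False),
}


@dataclass
class SubjectRecord:
    subject_id: str
    trial_id: str
    arm: str
    compound_program: str  # PALI or RIS
    modal_dose_mg: Optional[float]  # None for placebo
    treatment_group: str
    age: float
    sex: str  # female / male
    race: str  # white / other
    bmi: float
    baseline_panss_total: int
    baseline_cgi_s: int
    completed: bool
    discontinuation_week: Optional[int] = None
    prior_atypical_only: bool = False


@dataclass
class VisitRecord:
    subject_id: str
    week: int
    panss_total: int
    panss_factors: dict[str, int]
    cgi_s: Optional[int] = None
    weight_kg: Optional[float] = None


@dataclass
class AdverseEventRecord:
    subject_id: str
    preferred_term: str
    onset_week: int


SUBJECT_COLUMNS = [
    "subject_id", "trial_id", "arm", "compound_program", "modal_dose_mg",
    "treatment_group", "age", "sex", "race", "bmi", "baseline_panss_total",
    "baseline_cgi_s", "completed", "discontinuation_week",
    "prior_atypical_only",
]
VISIT_COLUMNS = (
    ["subject_id", "week", "panss_total"]
    + [f"panss_{f}" for f in PANSS_FACTORS]
    + ["cgi_s", "weight_kg"]
)
EVENT_COLUMNS = ["subject_id", "preferred_term", "onset_week"]


# ---------------------------------------------------------------------------
# validation

def validate_subject(rec: SubjectRecord, trials: Mapping[str, TrialMeta],
                     require_inclusion: bool = True) -> None:
    """Raise :class:`ValidationError` naming subject and field on violation.

    With ``require_inclusion`` the post-filter invariants (age 18-65) are
    enforced as well; raw pre-filter tables are read with it disabled.
    """

    def bad(field: str, msg: str) -> None:
        raise ValidationError(f"subject {rec.subject_id!r}: field {field!r} {msg}")

    if rec.trial_id not in trials:
        bad("trial_id", f"unknown trial {rec.trial_id!r}")
    if rec.compound_program not in (PALI, RIS):
        bad("compound_program", f"must be {PALI} or {RIS}")
    if rec.treatment_group not in TREATMENT_GROUPS:
        bad("treatment_group", f"unknown group {rec.treatment_group!r}")
    if rec.sex not in ("female", "male"):
        bad("sex", "must be 'female' or 'male'")
    if rec.race not in ("white", "other"):
        bad("race", "must be 'white' or 'other'")
    if not rec.bmi > 0:
        bad("bmi", "must be positive")
    if require_inclusion and not (18 <= rec.age <= 65):
        bad("age", f"value {rec.age} outside inclusion window [18, 65]")
    if not (30 <= rec.baseline_panss_total <= 210):
        bad("baseline_panss_total", "outside instrument range [30, 210]")
    lo, hi = trials[rec.trial_id].panss_entry_window
    if not (lo <= rec.baseline_panss_total <= hi):
        bad("baseline_panss_total",
            f"value {rec.baseline_panss_total} outside trial entry window [{lo}, {hi}]")
    if not (1 <= rec.baseline_cgi_s <= 7):
        bad("baseline_cgi_s", "outside scale range [1, 7]")
    if rec.completed and rec.discontinuation_week is not None:
        bad("discontinuation_week", "must be absent for completers")
    if not rec.completed and rec.discontinuation_week is None:
        bad("discontinuation_week", "required for non-completers")
    if rec.discontinuation_week is not None and rec.discontinuation_week < 0:
        bad("discontinuation_week", "must be >= 0")
    if rec.modal_dose_mg is not None and rec.modal_dose_mg <= 0:
        bad("modal_dose_mg", "must be positive when present")


def validate_visits(visits: Sequence[VisitRecord],
                    subjects: Sequence[SubjectRecord] | None = None) -> None:
    """Check per-subject visit-set invariants.

    Week 0 present, weeks strictly increasing, scale ranges, and (when the
    subject table is supplied) no post-discontinuation visits.
    """
    disc: dict[str, Optional[int]] = {}
    if subjects is not None:
        disc = {s.subject_id: s.discontinuation_week for s in subjects}
    by_subject: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_subject.setdefault(v.subject_id, []).append(v)
    for sid, vs in by_subject.items():
        weeks = [v.week for v in vs]
        if weeks != sorted(weeks) or len(set(weeks)) != len(weeks):
            raise ValidationError(f"subject {sid!r}: visit weeks not strictly increasing")
        if 0 not in weeks:
            raise ValidationError(f"subject {sid!r}: missing week-0 (baseline) visit")
        for v in vs:
            if v.week < 0:
                raise ValidationError(f"subject {sid!r}: negative visit week")
            if not (30 <= v.panss_total <= 210):
                raise ValidationError(
                    f"subject {sid!r}: field 'panss_total' outside [30, 210] at week {v.week}")
            if v.cgi_s is not None and not (1 <= v.cgi_s <= 7):
                raise ValidationError(
                    f"subject {sid!r}: field 'cgi_s' outside [1, 7] at week {v.week}")
            if v.weight_kg is not None and not v.weight_kg > 0:
                raise ValidationError(
                    f"subject {sid!r}: field 'weight_kg' must be positive")
        if sid in disc and disc[sid] is not None and max(weeks) > disc[sid]:
            raise ValidationError(f"subject {sid!r}: visit after discontinuation week")


def validate_events(events: Sequence[AdverseEventRecord],
                    visits: Sequence[VisitRecord]) -> None:
    last_week: dict[str, int] = {}
    for v in visits:
        last_week[v.subject_id] = max(last_week.get(v.subject_id, 0), v.week)
    for e in events:
        if e.subject_id not in last_week:
            raise ValidationError(
                f"event for unknown subject {e.subject_id!r}")
        if e.onset_week < 0 or e.onset_week > last_week[e.subject_id]:
            raise ValidationError(
                f"subject {e.subject_id!r}: field 'onset_week' outside observed period")


# ---------------------------------------------------------------------------
# readers / writers

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    return df


def _opt_float(cell: str) -> Optional[float]:
    return None if cell == "" else float(cell)


def _opt_int(cell: str) -> Optional[int]:
    return None if cell == "" else int(float(cell))


def _bool(cell: str) -> bool:
    if cell.lower() in ("true", "1"):
        return True
    if cell.lower() in ("false", "0"):
        return False
    raise ValidationError(f"cannot parse boolean cell {cell!r}")


def read_subject_table(path: str | Path,
                       trials: Mapping[str, TrialMeta] | None = None,
                       require_inclusion: bool = True) -> list[SubjectRecord]:
    """Read subjects.csv, validating each row; row order is preserved."""
    trials = DEFAULT_TRIALS if trials is None else trials
    df = _read_table(path, SUBJECT_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        rec = SubjectRecord(
            subject_id=row.subject_id,
            trial_id=row.trial_id,
            arm=row.arm,
            compound_program=row.compound_program,
            modal_dose_mg=_opt_float(row.modal_dose_mg),
            treatment_group=row.treatment_group,
            age=float(row.age),
            sex=row.sex,
            race=row.race,
            bmi=float(row.bmi),
            baseline_panss_total=int(float(row.baseline_panss_total)),
            baseline_cgi_s=int(float(row.baseline_cgi_s)),
            completed=_bool(row.completed),
            discontinuation_week=_opt_int(row.discontinuation_week),
            prior_atypical_only=_bool(row.prior_atypical_only),
        )
        validate_subject(rec, trials, require_inclusion=require_inclusion)
        records.append(rec)
    return records


def write_subject_table(records: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["completed"] = "true" if r.completed else "false"
        d["prior_atypical_only"] = "true" if r.prior_atypical_only else "false"
        rows.append(d)
    df = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    df.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_visit_table(path: str | Path) -> list[VisitRecord]:
    df = _read_table(path, VISIT_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(VisitRecord(
            subject_id=d["subject_id"],
            week=int(float(d["week"])),
            panss_total=int(float(d["panss_total"])),
            panss_factors={f: int(float(d[f"panss_{f}"])) for f in PANSS_FACTORS},
            cgi_s=_opt_int(d["cgi_s"]),
            weight_kg=_opt_float(d["weight_kg"]),
        ))
    return records


def write_visit_table(records: Iterable[VisitRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = {"subject_id": r.subject_id, "week": r.week, "panss_total": r.panss_total}
        for f in PANSS_FACTORS:
            d[f"panss_{f}"] = r.panss_factors[f]
        d["cgi_s"] = r.cgi_s
        d["weight_kg"] = r.weight_kg
        rows.append(d)
    pd.DataFrame(rows, columns=VISIT_COLUMNS).to_csv(
        path, index=False, na_rep="", encoding="utf-8")


def read_event_table(path: str | Path) -> list[AdverseEventRecord]:
    df = _read_table(path, EVENT_COLUMNS)
    return [AdverseEventRecord(row.subject_id, row.preferred_term,
                               int(float(row.onset_week)))
            for row in df.itertuples(index=False)]


def write_event_table(records: Iterable[AdverseEventRecord], path: str | Path) -> None:
    rows = [{"subject_id": r.subject_id, "preferred_term": r.preferred_term,
             "onset_week": r.onset_week} for r in records]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, index=False, na_rep="", encoding="utf-8")


# ---------------------------------------------------------------------------
# inclusion filtering and dose-group assignment

DEFAULT_FILTERS: dict[str, object] = {
    "age_min": 18.0,
    "age_max": 65.0,
    "max_risperidone_dose": 8.0,
    "exclude_prior_atypical_only": True,
}

_KNOWN_FILTER_KEYS = set(DEFAULT_FILTERS)

# modal-dose windows (inclusive) defining the analysis groups
PALI_DOSE_WINDOW = (6.0, 12.0)
RIS_2_4_WINDOW = (2.0, 4.0)
RIS_4_6_WINDOW = (4.0, 6.0)


def assign_treatment_group(rec: SubjectRecord) -> str:
    """Canonical group for one subject; 4 mg/day risperidone maps to RIS_2_4
    as its storage label while :func:`group_members` exposes the dual view."""
    if rec.modal_dose_mg is None:
        return PLACEBO_PALI if rec.compound_program == PALI else PLACEBO_RIS
    d = rec.modal_dose_mg
    if rec.compound_program == PALI:
        return PALI_6_12 if PALI_DOSE_WINDOW[0] <= d <= PALI_DOSE_WINDOW[1] else EXCLUDED
    if RIS_2_4_WINDOW[0] <= d <= RIS_2_4_WINDOW[1]:
        return RIS_2_4
    if RIS_4_6_WINDOW[0] < d <= RIS_4_6_WINDOW[1]:
        return RIS_4_6
    return EXCLUDED


def apply_inclusion_filters(subjects: Sequence[SubjectRecord],
                            filters: Mapping[str, object] | None = None,
                            ) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Apply the analysis inclusion screens and assign dose groups.

    Returns the retained subjects (with ``treatment_group`` assigned from
    modal dose) and an exclusion log with one row per dropped subject naming
    the first triggered rule.  Filtering is idempotent.
    """
    cfg = dict(DEFAULT_FILTERS)
    if filters:
        for key in filters:
            if key not in _KNOWN_FILTER_KEYS:
                raise ConfigError(f"unknown filter key {key!r}")
        cfg.update(filters)

    retained: list[SubjectRecord] = []
    log_rows: list[dict[str, str]] = []
    for rec in subjects:
        rule = None
        if rec.age > float(cfg["age_max"]):
            rule = f"age>{cfg['age_max']:g}"
        elif rec.age < float(cfg["age_min"]):
            rule = f"age<{cfg['age_min']:g}"
        elif (rec.compound_program == RIS and rec.modal_dose_mg is not None
              and rec.modal_dose_mg > float(cfg["max_risperidone_dose"])):
            rule = f"dose>{cfg['max_risperidone_dose']:g}"
        elif cfg["exclude_prior_atypical_only"] and rec.prior_atypical_only:
            rule = "prior_atypical_only"
        else:
            group = assign_treatment_group(rec)
            if group == EXCLUDED:
                rule = "dose_outside_defined_groups"
            else:
                retained.append(dataclasses.replace(rec, treatment_group=group))
        if rule is not None:
            log_rows.append({"subject_id": rec.subject_id, "rule": rule})
    log = pd.DataFrame(log_rows, columns=["subject_id", "rule"])
    return retained, log


def group_members(subjects: Sequence[SubjectRecord]) -> dict[str, list[str]]:
    """Subject-id views per analysis group.

    A risperidone subject with modal dose exactly 4 mg/day appears in both
    RIS_2_4 and RIS_4_6 (group views over one underlying subject set).
    """
    out: dict[str, list[str]] = {g: [] for g in TREATMENT_GROUPS if g != EXCLUDED}
    for rec in subjects:
        if rec.treatment_group in (PLACEBO_PALI, PLACEBO_RIS, PALI_6_12):
            out[rec.treatment_group].append(rec.subject_id)
        elif rec.treatment_group in (RIS_2_4, RIS_4_6):
            d = rec.modal_dose_mg
            if d is not None and RIS_2_4_WINDOW[0] <= d <= RIS_2_4_WINDOW[1]:
                out[RIS_2_4].append(rec.subject_id)
            if d is not None and RIS_4_6_WINDOW[0] <= d <= RIS_4_6_WINDOW[1]:
                out[RIS_4_6].append(rec.subject_id)
    return out


def subjects_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject records as a DataFrame indexed by subject_id."""
    df = pd.DataFrame([dataclasses.asdict(s) for s in subjects])
    return df.set_index("subject_id", drop=False)


def visits_frame(visits: Sequence[VisitRecord]) -> pd.DataFrame:
    rows = []
    for v in visits:
        d = {"subject_id": v.subject_id, "week": v.week,
             "panss_total": v.panss_total, "cgi_s": v.cgi_s,
             "weight_kg": v.weight_kg}
        for f in PANSS_FACTORS:
            d[f"panss_{f}"] = v.panss_factors[f]
        rows.append(d)
    return pd.DataFrame(rows)


def events_frame(events: Sequence[AdverseEventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": e.subject_id, "preferred_term": e.preferred_term,
          "onset_week": e.onset_week} for e in events],
        columns=EVENT_COLUMNS)
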