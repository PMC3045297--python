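"""Shared builders for compact patient-level test data."""

from __future__ import annotations

import pytest

from psbridge.trial_data import (
    SubjectRecord, VisitRecord, AdverseEventRecord, PANSS_FACTORS,
)


def make_subject(sid: str, **kw) -> SubjectRecord:
    """A valid paliperidone-program completer; override any field."""
    defaults = dict(
        subject_id=sid, trial_id="PALI-SCH-303", arm="paliperidone ER 6-12 mg",
        compound_program="PALI", modal_dose_mg=9.0, treatment_group="PALI_6_12",
        age=35.0, sex="male", race="white", bmi=25.0,
        baseline_panss_total=90, baseline_cgi_s=5, completed=True,
        discontinuation_week=None, prior_atypical_only=False,
    )
    defaults.update(kw)
    return SubjectRecord(**defaults)


def make_visit(sid: str, week: int, panss: int = 90, **kw) -> VisitRecord:
    factors = kw.pop("panss_factors", None)
    if factors is None:
        base = panss // 5
        factors = {f: base for f in PANSS_FACTORS}
        factors[PANSS_FACTORS[0]] += panss - 5 * base
    defaults = dict(subject_id=sid, week=week, panss_total=panss,
                    panss_factors=factors, cgi_s=5, weight_kg=75.0)
    defaults.update(kw)
    return VisitRecord(**defaults)


def make_event(sid: str, term: str = "insomnia", week: int = 1) -> AdverseEventRecord:
    return AdverseEventRecord(subject_id=sid, preferred_term=term, onset_week=week)


@pytest.fixture
def toy_subjects():
    return [make_subject(f"S{i:02d}") for i in range(5)]
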