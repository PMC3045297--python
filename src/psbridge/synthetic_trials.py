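"""Six-trial synthetic cohort generator.

Emulates the patient-level structure of two short-term placebo-controlled
antipsychotic trial programs so the whole matching/efficacy/safety pipeline
is testable without proprietary databases.  The default scenario suite is
calibrated to the published matched-group summaries: arm sizes, baseline
covariate moments, endpoint PANSS/CGI-S effects, completion rates, adverse
event incidences and weight changes.

Generation model
----------------
* Continuous baseline covariates are truncated normals whose location is
  numerically calibrated so the *truncated* (and, for integer scales, the
  rounded) mean equals the scenario target; binary covariates are Bernoulli.
* Each subject carries a latent total improvement ``delta`` drawn at the
  endpoint scale; the within-subject trajectory is linear, f(t) = t/W, with
  independent per-visit measurement noise.
* Dropout is outcome-independent by default: a constant discrete-time
  hazard h solved from (1-h)^W = completion_rate; visits after the last
  retained week are removed.  Because last-observation-carried-forward
  endpoints are attenuated under dropout, the latent effect is divided by
  the analytically computed attenuation E[L/W | L >= 1] so the realized
  mean LOCF change per arm equals ``endpoint_effect``.  An optional
  improvement-dependent hazard slope is provided to stress-test LOCF.
* Adverse events are independent Bernoulli draws per preferred term;
  factor scores partition the total change through fixed non-negative
  shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import trial_data as td
from ._util import round1
from .trial_data import (
    DEFAULT_TRIALS, PANSS_FACTORS, SubjectRecord, VisitRecord,
    AdverseEventRecord, TrialMeta,
    PALI, RIS, PALI_6_12, RIS_2_4, RIS_4_6, PLACEBO_PALI, PLACEBO_RIS,
)


class GenerationError(ValueError):
    """A scenario cannot be realized (e.g. unsatisfiable truncation window)."""


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline covariate moments for one arm (matched-group targets)."""

    age_mean: float
    age_sd: float
    female_prop: float
    white_prop: float
    bmi_mean: float
    bmi_sd: float
    panss_mean: float
    panss_sd: float
    cgi_mean: float
    cgi_sd: float


@dataclass(frozen=True)
class ArmScenario:
    trial_id: str
    label: str
    compound_program: str
    modal_dose_mg: Optional[float]
    n: int
    covariates: CovariateProfile
    endpoint_effect: float        # mean PANSS total change at endpoint (negative = improvement)
    effect_sd: float              # between-subject SD of total change
    factor_effect_shares: Mapping[str, float]
    cgi_effect: float
    completion_rate: float
    ae_rates: Mapping[str, float]
    weight_delta_kg: float

    def __post_init__(self) -> None:
        shares = self.factor_effect_shares
        if set(shares) != set(PANSS_FACTORS):
            raise ValueError(f"arm {self.label!r}: factor shares must cover {PANSS_FACTORS}")
        if any(v < 0 for v in shares.values()):
            raise ValueError(f"arm {self.label!r}: factor shares must be non-negative")
        if abs(sum(shares.values()) - 1.0) > 1e-8:
            raise ValueError(f"arm {self.label!r}: factor shares must sum to 1")
        if not (0.0 < self.completion_rate <= 1.0):
            raise ValueError(f"arm {self.label!r}: completion_rate outside (0, 1]")
        for term, p in self.ae_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"arm {self.label!r}: AE rate for {term!r} outside [0, 1]")


@dataclass(frozen=True)
class ScenarioSuite:
    trials: Mapping[str, TrialMeta]
    arms: Sequence[ArmScenario]
    seed: int = 0
    visit_noise_sd: float = 3.0       # PANSS points per visit
    cgi_effect_sd: float = 1.3
    cgi_noise_sd: float = 0.3
    weight_effect_sd: float = 4.0     # kg, between-subject SD of weight change
    weight_noise_sd: float = 0.3
    height_mean: float = 1.69         # m, used only to derive baseline weight from BMI
    height_sd: float = 0.09
    dropout_improvement_slope: float = 0.0  # optional hazard dependence on improvement

    def __post_init__(self) -> None:
        for arm in self.arms:
            if arm.trial_id not in self.trials:
                raise ValueError(f"arm {arm.label!r} references undeclared trial {arm.trial_id!r}")


# ---------------------------------------------------------------------------
# calibrated truncated-normal samplers

@lru_cache(maxsize=512)
def _calibrated_loc_continuous(target: float, sd: float, lo: float, hi: float) -> float:
    """Location mu such that a N(mu, sd) truncated to [lo, hi] has mean=target."""
    if not (lo < target < hi):
        raise GenerationError(
            f"target mean {target} outside truncation window [{lo}, {hi}]")

    def truncated_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd)

    return optimize.brentq(lambda mu: truncated_mean(mu) - target,
                           lo - 8 * sd, hi + 8 * sd, xtol=1e-10)


@lru_cache(maxsize=512)
def _calibrated_loc_integer(target: float, sd: float, lo: int, hi: int) -> float:
    """Location mu such that round(truncnorm on [lo-.5, hi+.5]) has mean=target."""
    if not (lo - 0.5 < target < hi + 0.5):
        raise GenerationError(
            f"target mean {target} outside integer window [{lo}, {hi}]")
    ks = np.arange(lo, hi + 1)

    def rounded_mean(mu: float) -> float:
        upper = stats.norm.cdf((ks + 0.5 - mu) / sd)
        lower = stats.norm.cdf((ks - 0.5 - mu) / sd)
        z = upper[-1] - lower[0]
        if z <= 0:
            return lo if mu < lo else hi
        return float(np.sum(ks * (upper - lower)) / z)

    return optimize.brentq(lambda mu: rounded_mean(mu) - target,
                           lo - 8 * sd, hi + 8 * sd, xtol=1e-10)


def _draw_truncnorm(rng: np.random.Generator, target: float, sd: float,
                    lo: float, hi: float, n: int) -> np.ndarray:
    mu = _calibrated_loc_continuous(float(target), float(sd), float(lo), float(hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def _draw_truncnorm_int(rng: np.random.Generator, target: float, sd: float,
                        lo: int, hi: int, n: int) -> np.ndarray:
    mu = _calibrated_loc_integer(float(target), float(sd), int(lo), int(hi))
    a, b = (lo - 0.5 - mu) / sd, (hi + 0.5 - mu) / sd
    x = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(x).astype(int), lo, hi)


# ---------------------------------------------------------------------------
# dropout / LOCF attenuation

def dropout_hazard(completion_rate: float, weeks: int) -> float:
    """Constant weekly hazard with survival to endpoint = completion_rate."""
    if completion_rate >= 1.0:
        return 0.0
    return 1.0 - completion_rate ** (1.0 / weeks)


def locf_attenuation(completion_rate: float, weeks: int) -> float:
    """E[L/W | L >= 1] for last retained week L under constant hazard.

    This is the factor by which a linear-gain latent effect is shrunk in a
    last-observation-carried-forward analysis restricted to subjects with at
    least one post-baseline visit.
    """
    h = dropout_hazard(completion_rate, weeks)
    if h == 0.0:
        return 1.0
    s = 1.0 - h
    p = [s**k * h for k in range(weeks)] + [s**weeks]  # P(L = 0..W)
    num = sum(k * p[k] for k in range(1, weeks + 1))
    den = sum(p[k] for k in range(1, weeks + 1))
    return (num / den) / weeks


def _partition_int(total: int, weights: np.ndarray) -> np.ndarray:
    """Split a non-negative integer into parts proportional to weights,
    largest-remainder rule; parts sum exactly to total."""
    raw = weights * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


# ---------------------------------------------------------------------------
# the default suite: published matched-group summaries as targets

_FACTOR_ORDER = np.array(PANSS_FACTORS)
_ITEM_SHARES = np.array([7, 8, 4, 7, 4]) / 30.0  # items per factor / 30


def _shares(raw: Sequence[float]) -> dict[str, float]:
    v = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    v = v / v.sum()
    return dict(zip(PANSS_FACTORS, v))


# group-level targets: (effect, effect_sd, shares, cgi, completion, weight)
_GROUP_EFFECTS = {
    PALI_6_12:    (-18.4, 22.7, _shares([4.7, 6.2, 2.3, 3.5, 1.4]), -0.9, 0.648, 0.7),
    RIS_2_4:      (-11.6, 23.4, _shares([2.5, 4.5, 1.7, 2.3, 0.6]), 0.0, 0.540, 1.0),
    RIS_4_6:      (-18.7, 22.5, _shares([3.8, 6.3, 2.5, 4.2, 2.0]), -0.1, 0.667, 1.3),
    PLACEBO_PALI: (-6.5, 24.0, _shares([1.3, 2.5, 1.3, 1.2, 0.0]), -0.2, 0.368, 0.0),
    PLACEBO_RIS:  (-5.4, 24.0, _shares([2.3, 1.6, 1.8, 0.6, 0.0]), -0.2, 0.516, 0.0),
}

_GROUP_COVARIATES = {
    PALI_6_12:    CovariateProfile(37.4, 11.3, 0.251, 0.760, 25.2, 4.7, 94.3, 11.9, 4.8, 0.7),
    RIS_2_4:      CovariateProfile(37.8, 10.6, 0.274, 0.735, 25.5, 3.3, 94.4, 15.2, 4.8, 0.6),
    RIS_4_6:      CovariateProfile(37.1, 10.1, 0.248, 0.767, 25.5, 3.4, 96.2, 16.6, 4.8, 0.7),
    # white_prop uses the pooled-placebo proportion (63.6%); the per-group
    # printed race percentages have inconsistent denominators (see docs)
    PLACEBO_PALI: CovariateProfile(36.7, 10.9, 0.242, 0.636, 24.9, 5.2, 94.5, 12.2, 4.6, 0.7),
    PLACEBO_RIS:  CovariateProfile(38.0, 10.1, 0.148, 0.636, 25.3, 3.2, 92.6, 12.3, 4.7, 0.8),
}

# published treatment-emergent AE incidences (%) per matched group
_AE_PCTS = {
    "insomnia":                (14.5, 9.5, 22.1, 17.1, 18.9),
    "sinus tachycardia":       (7.8, 4.2, 0.9, 1.6, 0.0),
    "tachycardia":             (6.7, 3.2, 0.9, 2.3, 0.0),
    "somnolence":              (3.9, 5.3, 8.9, 7.0, 1.6),
    "restlessness":            (0.0, 0.0, 8.0, 5.4, 0.8),
    "nausea":                  (2.2, 4.2, 8.0, 8.5, 3.3),
    "anxiety":                 (1.7, 2.1, 9.7, 10.9, 5.7),
    "salivary hypersecretion": (1.7, 0.0, 5.3, 3.9, 0.0),
    "akathisia":               (4.5, 3.2, 4.4, 4.7, 0.8),
    "dizziness":               (4.5, 3.2, 4.4, 6.2, 2.5),
    "nasal congestion":        (0.6, 0.0, 3.5, 5.4, 2.5),
}
_AE_GROUP_INDEX = {PALI_6_12: 0, PLACEBO_PALI: 1, RIS_2_4: 2, RIS_4_6: 3,
                   PLACEBO_RIS: 4}

# risperidone dose-stratum sizes: modal 2-3 mg (2-4 group only), exactly 4 mg
# (both groups), 5-6 mg (4-6 group only)
_N_23, _N_4, _N_56 = 50, 63, 66
_N_24, _N_46 = 113, 129


def _stratum_solve(v24: float, v46: float) -> tuple[float, float, float]:
    """Dose-stratum values consistent with both overlapping group means.

    The 4 mg stratum (shared by both groups) is set to the midpoint of the
    group targets; the outer strata are solved from the group-mean identities
    n23*v23 + n4*v4 = n24*v24 and n4*v4 + n56*v56 = n46*v46.
    """
    v4 = (v24 + v46) / 2.0
    v23 = (_N_24 * v24 - _N_4 * v4) / _N_23
    v56 = (_N_46 * v46 - _N_4 * v4) / _N_56
    return v23, v4, v56


def _stratum_ae_rates() -> tuple[dict, dict, dict]:
    r23, r4, r56 = {}, {}, {}
    for term, pct in _AE_PCTS.items():
        a, b, c = _stratum_solve(pct[2] / 100.0, pct[3] / 100.0)
        r23[term] = min(max(a, 0.0), 1.0)
        r4[term] = min(max(b, 0.0), 1.0)
        r56[term] = min(max(c, 0.0), 1.0)
    return r23, r4, r56


def _avg_profile(a: CovariateProfile, b: CovariateProfile) -> CovariateProfile:
    return CovariateProfile(*[(x + y) / 2.0 for x, y in
                              zip(a.__dict__.values(), b.__dict__.values())])


def default_suite(seed: int = 0) -> ScenarioSuite:
    """The six-trial scenario suite calibrated to the published summaries.

    Arm sizes reproduce the matched analysis population (179 paliperidone ER
    6-12 mg/day, 113 risperidone 2-4 mg/day, 129 risperidone 4-6 mg/day with
    63 subjects at 4 mg/day shared between the risperidone groups, 95 and
    122 program placebo subjects).  Risperidone dose-stratum parameters are
    solved so both overlapping dose-group means hit their printed targets.
    """
    arms: list[ArmScenario] = []

    def group_ae(group: str) -> dict[str, float]:
        i = _AE_GROUP_INDEX[group]
        return {t: p[i] / 100.0 for t, p in _AE_PCTS.items()}

    def add(trial: str, label: str, program: str, dose: Optional[float],
            n: int, group: str, *, effect=None, shares=None, cgi=None,
            completion=None, weight=None, ae=None, cov=None) -> None:
        g_eff, g_sd, g_shares, g_cgi, g_comp, g_w = _GROUP_EFFECTS[group]
        arms.append(ArmScenario(
            trial_id=trial, label=label, compound_program=program,
            modal_dose_mg=dose, n=n,
            covariates=cov if cov is not None else _GROUP_COVARIATES[group],
            endpoint_effect=g_eff if effect is None else effect,
            effect_sd=g_sd,
            factor_effect_shares=g_shares if shares is None else shares,
            cgi_effect=g_cgi if cgi is None else cgi,
            completion_rate=g_comp if completion is None else completion,
            ae_rates=group_ae(group) if ae is None else ae,
            weight_delta_kg=g_w if weight is None else weight,
        ))

    # paliperidone ER program: 3 six-week trials
    add("PALI-SCH-303", "paliperidone ER 6-12 mg", PALI, 9.0, 60, PALI_6_12)
    add("PALI-SCH-304", "paliperidone ER 6-12 mg", PALI, 9.0, 60, PALI_6_12)
    add("PALI-SCH-305", "paliperidone ER 6-12 mg", PALI, 9.0, 59, PALI_6_12)
    add("PALI-SCH-303", "placebo", PALI, None, 32, PLACEBO_PALI)
    add("PALI-SCH-304", "placebo", PALI, None, 32, PLACEBO_PALI)
    add("PALI-SCH-305", "placebo", PALI, None, 31, PLACEBO_PALI)

    # risperidone program: dose strata solved for overlap consistency
    e23, e4, e56 = _stratum_solve(_GROUP_EFFECTS[RIS_2_4][0], _GROUP_EFFECTS[RIS_4_6][0])
    c23, c4, c56 = _stratum_solve(_GROUP_EFFECTS[RIS_2_4][4], _GROUP_EFFECTS[RIS_4_6][4])
    g23, g4, g56 = _stratum_solve(_GROUP_EFFECTS[RIS_2_4][3], _GROUP_EFFECTS[RIS_4_6][3])
    w23, w4, w56 = _stratum_solve(_GROUP_EFFECTS[RIS_2_4][5], _GROUP_EFFECTS[RIS_4_6][5])
    a23, a4, a56 = _stratum_ae_rates()
    sh24 = _GROUP_EFFECTS[RIS_2_4][2]
    sh46 = _GROUP_EFFECTS[RIS_4_6][2]
    sh4 = _shares([(sh24[f] + sh46[f]) / 2 for f in PANSS_FACTORS])
    cov24, cov46 = _GROUP_COVARIATES[RIS_2_4], _GROUP_COVARIATES[RIS_4_6]
    cov4 = _avg_profile(cov24, cov46)
    kw23 = dict(effect=e23, shares=sh24, cgi=g23, completion=min(max(c23, 0.05), 1.0),
                weight=w23, ae=a23, cov=cov24)
    kw4 = dict(effect=e4, shares=sh4, cgi=g4, completion=min(max(c4, 0.05), 1.0),
               weight=w4, ae=a4, cov=cov4)
    kw56 = dict(effect=e56, shares=sh46, cgi=g56, completion=min(max(c56, 0.05), 1.0),
                weight=w56, ae=a56, cov=cov46)

    add("RIS-USA-1", "risperidone flexible, modal 3 mg", RIS, 3.0, 25, RIS_2_4, **kw23)
    add("RIS-USA-1", "risperidone flexible, modal 4 mg", RIS, 4.0, 20, RIS_2_4, **kw4)
    add("RIS-USA-1", "risperidone flexible, modal 5 mg", RIS, 5.0, 26, RIS_4_6, **kw56)
    add("RIS-INT-3", "risperidone 2 mg", RIS, 2.0, 25, RIS_2_4, **kw23)
    add("RIS-INT-3", "risperidone 6 mg", RIS, 6.0, 40, RIS_4_6, **kw56)
    add("RIS-USA-72", "risperidone 4 mg", RIS, 4.0, 43, RIS_2_4, **kw4)
    add("RIS-USA-1", "placebo", RIS, None, 40, PLACEBO_RIS)
    add("RIS-INT-3", "placebo", RIS, None, 42, PLACEBO_RIS)
    add("RIS-USA-72", "placebo", RIS, None, 40, PLACEBO_RIS)

    return ScenarioSuite(trials=dict(DEFAULT_TRIALS), arms=tuple(arms), seed=seed)


def with_covariate_shift(suite: ScenarioSuite, program: str,
                         age_shift: float = 0.0, bmi_shift: float = 0.0,
                         panss_shift: float = 0.0) -> ScenarioSuite:
    """Suite variant with shifted covariate means in one compound program.

    Induces a known confounded assignment for matching stress tests."""
    arms = []
    for arm in suite.arms:
        if arm.compound_program == program:
            c = arm.covariates
            arms.append(replace(arm, covariates=replace(
                c, age_mean=c.age_mean + age_shift,
                bmi_mean=c.bmi_mean + bmi_shift,
                panss_mean=c.panss_mean + panss_shift)))
        else:
            arms.append(arm)
    return replace(suite, arms=tuple(arms))


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(suite: ScenarioSuite, seed: Optional[int] = None,
                    ) -> tuple[list[SubjectRecord], list[VisitRecord],
                               list[AdverseEventRecord]]:
    """Draw one patient-level six-trial cohort; fixed seed -> identical output."""
    rng = np.random.default_rng(suite.seed if seed is None else seed)
    subjects: list[SubjectRecord] = []
    visits: list[VisitRecord] = []
    events: list[AdverseEventRecord] = []

    for arm_idx, arm in enumerate(suite.arms):
        if arm.n == 0:
            continue
        trial = suite.trials[arm.trial_id]
        W = trial.endpoint_week
        n = arm.n
        cov = arm.covariates
        lo, hi = trial.panss_entry_window
        try:
            age = _draw_truncnorm(rng, cov.age_mean, cov.age_sd, 18.0, 65.0, n)
            female = rng.random(n) < cov.female_prop
            white = rng.random(n) < cov.white_prop
            bmi = _draw_truncnorm(rng, cov.bmi_mean, cov.bmi_sd, 16.0, 45.0, n)
            panss0 = _draw_truncnorm_int(rng, cov.panss_mean, cov.panss_sd, lo, hi, n)
            cgi0 = _draw_truncnorm_int(rng, cov.cgi_mean, cov.cgi_sd, 1, 7, n)
        except GenerationError as exc:
            raise GenerationError(f"arm {arm.label!r} in {arm.trial_id}: {exc}") from exc
        height = _draw_truncnorm(rng, suite.height_mean, suite.height_sd, 1.45, 2.05, n)

        h = dropout_hazard(arm.completion_rate, W)
        if h == 0.0:
            last_week = np.full(n, W, dtype=int)
        else:
            g = rng.geometric(h, size=n)  # 1-based week of dropout
            last_week = np.minimum(g - 1, W)

        atten = locf_attenuation(arm.completion_rate, W)
        delta = rng.normal(arm.endpoint_effect / atten, arm.effect_sd, n)
        delta_cgi = rng.normal(arm.cgi_effect / atten, suite.cgi_effect_sd, n)
        delta_w = rng.normal(arm.weight_delta_kg / atten, suite.weight_effect_sd, n)

        if suite.dropout_improvement_slope != 0.0 and h > 0.0:
            # optional outcome-dependent dropout: subjects improving less than
            # the arm mean drop out earlier (hazard scaled linearly)
            rel = (delta - delta.mean()) / max(arm.effect_sd, 1e-9)
            h_i = np.clip(h * (1.0 + suite.dropout_improvement_slope * rel), 1e-6, 0.999)
            u = rng.random((n, W))
            surv = np.cumprod(u >= h_i[:, None], axis=1)
            last_week = surv.sum(axis=1).astype(int)

        eps = rng.normal(0.0, suite.visit_noise_sd, (n, W + 1))
        eps_c = rng.normal(0.0, suite.cgi_noise_sd, (n, W + 1))
        eps_w = rng.normal(0.0, suite.weight_noise_sd, (n, W + 1))

        shares = np.array([arm.factor_effect_shares[f] for f in PANSS_FACTORS])

        term_hits: dict[str, np.ndarray] = {}
        term_onsets: dict[str, np.ndarray] = {}
        for term in sorted(arm.ae_rates):
            rate = arm.ae_rates[term]
            term_hits[term] = rng.random(n) < rate
            draw = rng.integers(1, W + 1, size=n)
            term_onsets[term] = np.minimum(draw, last_week)

        for i in range(n):
            sid = f"{arm.trial_id}:{arm_idx:02d}:{i:03d}"
            L = int(last_week[i])
            completed = L == W
            rec = SubjectRecord(
                subject_id=sid, trial_id=arm.trial_id, arm=arm.label,
                compound_program=arm.compound_program,
                modal_dose_mg=arm.modal_dose_mg,
                treatment_group="EXCLUDED",  # assigned below from modal dose
                age=float(np.round(age[i], 1)), sex="female" if female[i] else "male",
                race="white" if white[i] else "other",
                bmi=float(np.round(bmi[i], 1)),
                baseline_panss_total=int(panss0[i]),
                baseline_cgi_s=int(cgi0[i]),
                completed=completed,
                discontinuation_week=None if completed else L,
            )
            rec.treatment_group = td.assign_treatment_group(rec)
            subjects.append(rec)

            f0 = _partition_int(int(panss0[i]), _ITEM_SHARES)
            w0 = bmi[i] * height[i] ** 2
            for t in range(0, L + 1):
                if t == 0:
                    total = int(panss0[i])
                else:
                    total = int(np.clip(round(panss0[i] + delta[i] * t / W + eps[i, t]),
                                        30, 210))
                change = total - int(panss0[i])
                raw = shares * change
                parts = np.rint(raw).astype(int)
                parts[int(np.argmax(shares))] += change - parts.sum()
                factors = {f: int(f0[k] + parts[k]) for k, f in enumerate(PANSS_FACTORS)}
                if trial.has_cgi:
                    cgi_val = int(np.clip(round(cgi0[i] + delta_cgi[i] * t / W
                                                + (0.0 if t == 0 else eps_c[i, t])), 1, 7))
                else:
                    cgi_val = None
                wt = float(np.round(w0 + delta_w[i] * t / W
                                    + (0.0 if t == 0 else eps_w[i, t]), 2))
                visits.append(VisitRecord(
                    subject_id=sid, week=t, panss_total=total,
                    panss_factors=factors, cgi_s=cgi_val, weight_kg=wt))

            for term in sorted(arm.ae_rates):
                if term_hits[term][i]:
                    events.append(AdverseEventRecord(
                        subject_id=sid, preferred_term=term,
                        onset_week=int(term_onsets[term][i])))

    return subjects, visits, events


# ---------------------------------------------------------------------------
# cohort summaries (layout mirrors the published baseline/safety tables)

def summarize_cohort(subjects: Sequence[SubjectRecord],
                     visits: Sequence[VisitRecord],
                     events: Sequence[AdverseEventRecord],
                     ) -> dict[str, pd.DataFrame]:
    """Per-group covariate moments, completion, and AE incidences."""
    from .safety import incidence_table  # local import avoids cycle at import time

    groups = td.group_members(subjects)
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for g, ids in groups.items():
        if not ids:
            continue
        recs = [by_id[i] for i in ids]
        n = len(recs)

        def msd(vals):
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
            return mean, sd

        age_m, age_s = msd([r.age for r in recs])
        bmi_m, bmi_s = msd([r.bmi for r in recs])
        pan_m, pan_s = msd([r.baseline_panss_total for r in recs])
        cgi_m, cgi_s = msd([r.baseline_cgi_s for r in recs])
        nf = sum(r.sex == "female" for r in recs)
        nw = sum(r.race == "white" for r in recs)
        nc = sum(r.completed for r in recs)
        rows.append({
            "group": g, "n": n,
            "age_mean": age_m, "age_sd": age_s,
            "female_n": nf, "female_pct": round1(100.0 * nf / n),
            "white_n": nw, "white_pct": round1(100.0 * nw / n),
            "bmi_mean": bmi_m, "bmi_sd": bmi_s,
            "panss_mean": pan_m, "panss_sd": pan_s,
            "cgi_mean": cgi_m, "cgi_sd": cgi_s,
            "completed_n": nc, "completion_pct": round1(100.0 * nc / n),
        })
    group_df = pd.DataFrame(rows).set_index("group")
    ae_df = incidence_table(events, {g: ids for g, ids in groups.items() if ids})
    return {"groups": group_df, "adverse_events": ae_df}
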