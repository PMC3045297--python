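"""Propensity models, greedy hierarchical caliper matching, and the
three-step construction of the matched analysis population.

The propensity score is the fitted probability from a logistic regression
of group membership on age, sex, race (white vs all other), baseline BMI,
baseline CGI-S and baseline PANSS total.  Matching is 1-to-many with a
caliper of 0.05 on the probability scale: in each pass every case (the
smaller group) claims its nearest still-unclaimed control within the
caliper, best matches first pass, next-best in later passes, until a pass
adds no pair.  The matched population is built in three steps: risperidone
vs its placebo, paliperidone ER vs its placebo, then a refitted
cross-compound model on the survivors; all subjects matched in the final
cross-compound pairing enter the analysis sample together with the
program-specific placebo groups retained in steps 1-2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import trial_data as td
from .trial_data import (
    SubjectRecord, PALI, RIS,
    PALI_6_12, RIS_2_4, RIS_4_6, PLACEBO_PALI, PLACEBO_RIS,
)

DEFAULT_COVARIATES = ("age", "sex", "race", "bmi", "baseline_cgi_s",
                      "baseline_panss_total")

DEFAULT_CALIPER = 0.05


class MatchingError(ValueError):
    """Propensity fitting or cohort construction failed."""


@dataclass
class PropensityModel:
    covariates: tuple[str, ...]
    params: pd.Series
    converged: bool
    deviance: float
    scores: pd.Series                # fitted probabilities by subject_id
    dropped_subjects: list[str]      # incomplete covariate rows
    dropped_covariates: list[str]    # zero-variance columns removed pre-fit


@dataclass(frozen=True)
class MatchPair:
    case_id: str
    control_id: str
    case_score: float
    control_score: float
    distance: float
    pass_index: int


@dataclass
class MatchResult:
    caliper: float
    pairs: list[MatchPair]
    unmatched_cases: list[str]
    unmatched_controls: list[str]

    @property
    def matched_case_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.case_id)
        return list(seen)

    @property
    def matched_control_ids(self) -> list[str]:
        return [p.control_id for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"case_id": p.case_id, "control_id": p.control_id,
              "case_score": p.case_score, "control_score": p.control_score,
              "distance": p.distance, "pass_index": p.pass_index}
             for p in self.pairs],
            columns=["case_id", "control_id", "case_score", "control_score",
                     "distance", "pass_index"])


@dataclass
class MatchedPopulation:
    groups: dict[str, list[str]]
    pooled_placebo: bool = False
    provenance: dict = field(default_factory=dict)

    def group_sizes(self) -> dict[str, int]:
        return {g: len(ids) for g, ids in self.groups.items()}


# ---------------------------------------------------------------------------
# propensity model

def _design_frame(subjects: Sequence[SubjectRecord],
                  covariates: Sequence[str]) -> pd.DataFrame:
    df = td.subjects_frame(subjects)
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        if c == "sex":
            X["female"] = (df["sex"] == "female").astype(float)
        elif c == "race":
            X["white"] = (df["race"] == "white").astype(float)
        else:
            X[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    return X


def fit_propensity(subjects: Sequence[SubjectRecord],
                   indicator: Mapping[str, int],
                   covariates: Sequence[str] = DEFAULT_COVARIATES,
                   ) -> PropensityModel:
    """Maximum-likelihood logistic fit; scores are fitted probabilities.

    ``indicator`` maps subject_id -> 0/1 group membership.  Subjects with
    any missing covariate are dropped and logged; zero-variance covariate
    columns are removed (the intercept absorbs them).
    """
    subjects = [s for s in subjects if s.subject_id in indicator]
    X = _design_frame(subjects, covariates)
    y = pd.Series({s.subject_id: int(indicator[s.subject_id]) for s in subjects},
                  dtype=float).reindex(X.index)

    complete = X.notna().all(axis=1)
    dropped_subjects = list(X.index[~complete])
    X, y = X.loc[complete], y.loc[complete]

    if y.nunique() < 2:
        raise MatchingError("both levels of the group indicator are required")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise MatchingError("need at least 2 subjects per level of the indicator")
    if len(X) < len(covariates) + 2:
        raise MatchingError(
            f"too few subjects ({len(X)}) for {len(covariates)} covariates")

    dropped_covariates = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped_covariates)
    exog = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(method="newton", maxiter=200, disp=0)
        except Exception as exc:  # statsmodels raises on hard separation
            raise MatchingError(
                "logistic fit failed (possible perfect separation); "
                f"review the covariate set: {exc}") from exc
    linpred = np.asarray(exog @ res.params, dtype=float)
    if not np.all(np.isfinite(res.params)) or np.abs(linpred).max() > 30.0:
        # fitted probabilities numerically at 0/1 imply (quasi-)separation
        raise MatchingError(
            "perfect separation detected; review the covariate set")

    scores = pd.Series(res.predict(exog), index=X.index, name="propensity")
    eps = 1e-12
    scores = scores.clip(eps, 1 - eps)
    return PropensityModel(
        covariates=tuple(covariates),
        params=res.params,
        converged=bool(res.mle_retvals.get("converged", True)),
        deviance=float(-2.0 * res.llf),
        scores=scores,
        dropped_subjects=dropped_subjects,
        dropped_covariates=dropped_covariates,
    )


# ---------------------------------------------------------------------------
# greedy hierarchical caliper matching

def greedy_caliper_match(cases: Mapping[str, float] | Sequence[tuple[str, float]],
                         controls: Mapping[str, float] | Sequence[tuple[str, float]],
                         caliper: float = DEFAULT_CALIPER,
                         max_ratio: Optional[int] = None) -> MatchResult:
    """Pass-structured greedy 1-to-many matching.

    Each pass iterates cases in ascending id order; a case claims the
    nearest unclaimed control with |score difference| <= caliper (ties
    broken toward the lower control id).  Passes repeat, each case gaining
    at most one control per pass, until a pass adds no pair or every case
    holds ``max_ratio`` controls.  Deterministic given its inputs; empty
    inputs yield an empty result.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    case_items = sorted(dict(cases).items())
    control_items = sorted(dict(controls).items())
    for _, s in case_items + control_items:
        if not (0.0 < s < 1.0):
            raise ValueError("propensity scores must lie strictly in (0, 1)")

    unclaimed = dict(control_items)
    pairs: list[MatchPair] = []
    per_case: dict[str, int] = {cid: 0 for cid, _ in case_items}
    pass_index = 0
    while unclaimed:
        pass_index += 1
        added = 0
        for cid, cscore in case_items:
            if max_ratio is not None and per_case[cid] >= max_ratio:
                continue
            best: Optional[tuple[float, str]] = None
            for kid, kscore in unclaimed.items():
                d = abs(cscore - kscore)
                if d <= caliper and (best is None or (d, kid) < best):
                    best = (d, kid)
            if best is not None:
                d, kid = best
                pairs.append(MatchPair(cid, kid, cscore, unclaimed[kid], d, pass_index))
                del unclaimed[kid]
                per_case[cid] += 1
                added += 1
        if added == 0:
            break
    matched_cases = {p.case_id for p in pairs}
    return MatchResult(
        caliper=caliper,
        pairs=pairs,
        unmatched_cases=[cid for cid, _ in case_items if cid not in matched_cases],
        unmatched_controls=sorted(unclaimed),
    )


# ---------------------------------------------------------------------------
# three-step matched population

def _match_step(subjects_a: list[SubjectRecord], subjects_b: list[SubjectRecord],
                caliper: float, covariates: Sequence[str],
                max_ratio: Optional[int], step_name: str,
                ) -> tuple[set[str], set[str], dict]:
    """Fit a propensity model on A vs B and match with A=indicator 1.

    Cases are the smaller side (1-to-many growth maximizes retention).
    Returns (retained ids of A, retained ids of B, provenance).
    """
    if not subjects_a or not subjects_b:
        raise MatchingError(f"{step_name}: empty group")
    indicator = {s.subject_id: 1 for s in subjects_a}
    indicator.update({s.subject_id: 0 for s in subjects_b})
    model = fit_propensity(subjects_a + subjects_b, indicator, covariates)
    ids_a = [s.subject_id for s in subjects_a if s.subject_id in model.scores.index]
    ids_b = [s.subject_id for s in subjects_b if s.subject_id in model.scores.index]
    side_a = {i: float(model.scores[i]) for i in ids_a}
    side_b = {i: float(model.scores[i]) for i in ids_b}
    if len(side_a) <= len(side_b):
        result = greedy_caliper_match(side_a, side_b, caliper, max_ratio)
        kept_a = set(result.matched_case_ids)
        kept_b = set(result.matched_control_ids)
    else:
        result = greedy_caliper_match(side_b, side_a, caliper, max_ratio)
        kept_b = set(result.matched_case_ids)
        kept_a = set(result.matched_control_ids)
    if not kept_a or not kept_b:
        raise MatchingError(f"{step_name}: no matches within caliper {caliper}")
    prov = {
        "step": step_name,
        "n_pairs": len(result.pairs),
        "n_retained_1": len(kept_a),
        "n_retained_0": len(kept_b),
        "dropped_incomplete": model.dropped_subjects,
        "deviance": model.deviance,
    }
    return kept_a, kept_b, prov


def build_matched_population(subjects: Sequence[SubjectRecord],
                             caliper: float = DEFAULT_CALIPER,
                             covariates: Sequence[str] = DEFAULT_COVARIATES,
                             max_ratio: Optional[int] = None,
                             ) -> MatchedPopulation:
    """Three-step matched cohort construction.

    1. risperidone (all doses) vs placebo from the risperidone trials;
    2. paliperidone ER vs placebo from the paliperidone trials;
    3. a propensity model refit on the step-1/2 active survivors with
       compound program as the outcome, matched across compounds.  All
       subjects in the final cross-compound pairing are retained, alongside
       the step-1/2 placebo groups.
    """
    by_id = {s.subject_id: s for s in subjects}
    ris_active = [s for s in subjects
                  if s.treatment_group in (RIS_2_4, RIS_4_6)]
    pali_active = [s for s in subjects if s.treatment_group == PALI_6_12]
    plc_ris = [s for s in subjects if s.treatment_group == PLACEBO_RIS]
    plc_pali = [s for s in subjects if s.treatment_group == PLACEBO_PALI]

    kept_ris, kept_plc_ris, prov1 = _match_step(
        ris_active, plc_ris, caliper, covariates, max_ratio,
        "step 1 (risperidone vs placebo[RIS])")
    kept_pali, kept_plc_pali, prov2 = _match_step(
        pali_active, plc_pali, caliper, covariates, max_ratio,
        "step 2 (paliperidone ER vs placebo[PALI])")

    surv_pali = [by_id[i] for i in sorted(kept_pali)]
    surv_ris = [by_id[i] for i in sorted(kept_ris)]
    final_pali, final_ris, prov3 = _match_step(
        surv_pali, surv_ris, caliper, covariates, max_ratio,
        "step 3 (cross-compound)")

    dual = td.group_members([by_id[i] for i in sorted(final_ris)])
    groups = {
        PALI_6_12: sorted(final_pali),
        RIS_2_4: sorted(dual[RIS_2_4]),
        RIS_4_6: sorted(dual[RIS_4_6]),
        PLACEBO_PALI: sorted(kept_plc_pali),
        PLACEBO_RIS: sorted(kept_plc_ris),
    }
    for g, ids in groups.items():
        if not ids:
            raise MatchingError(f"matched population: group {g} is empty")
    return MatchedPopulation(groups=groups, pooled_placebo=False,
                             provenance={"steps": [prov1, prov2, prov3],
                                         "caliper": caliper})


# ---------------------------------------------------------------------------
# balance diagnostics

_BALANCE_COVARIATES = (
    ("age", "continuous"),
    ("female", "binary"),
    ("white", "binary"),
    ("bmi", "continuous"),
    ("baseline_panss_total", "continuous"),
    ("baseline_cgi_s", "continuous"),
)


@dataclass
class BalanceTable:
    stats: pd.DataFrame  # per group: mean/sd or n/%
    smd: pd.DataFrame    # absolute standardized mean differences, pairwise


def _covariate_matrix(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    df = td.subjects_frame(subjects)
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"].astype(float)
    out["female"] = (df["sex"] == "female").astype(float)
    out["white"] = (df["race"] == "white").astype(float)
    out["bmi"] = df["bmi"].astype(float)
    out["baseline_panss_total"] = df["baseline_panss_total"].astype(float)
    out["baseline_cgi_s"] = df["baseline_cgi_s"].astype(float)
    return out


def standardized_mean_difference(x: np.ndarray, y: np.ndarray,
                                 binary: bool = False) -> float:
    """|mean difference| / pooled SD; 0 when both spreads vanish."""
    mx, my = float(np.mean(x)), float(np.mean(y))
    if binary:
        vx, vy = mx * (1 - mx), my * (1 - my)
    else:
        vx = float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
        vy = float(np.var(y, ddof=1)) if len(y) > 1 else 0.0
    denom = math.sqrt((vx + vy) / 2.0)
    if mx == my:
        return 0.0
    if denom == 0.0:
        return float("inf")
    return abs(mx - my) / denom


def balance_table(subjects: Sequence[SubjectRecord],
                  groups: Mapping[str, Sequence[str]]) -> BalanceTable:
    """Covariate summary per group plus pairwise absolute SMDs."""
    X = _covariate_matrix(subjects)
    stats_rows = []
    for g, ids in groups.items():
        sub = X.loc[list(ids)]
        row = {"group": g, "n": len(sub)}
        for cov, kind in _BALANCE_COVARIATES:
            if kind == "binary":
                row[f"{cov}_n"] = int(sub[cov].sum())
                row[f"{cov}_pct"] = 100.0 * sub[cov].mean() if len(sub) else np.nan
            else:
                row[f"{cov}_mean"] = sub[cov].mean()
                row[f"{cov}_sd"] = sub[cov].std(ddof=1) if len(sub) > 1 else np.nan
        stats_rows.append(row)
    stats_df = pd.DataFrame(stats_rows).set_index("group")

    names = list(groups)
    smd_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa = X.loc[list(groups[a])]
            xb = X.loc[list(groups[b])]
            row = {"group_a": a, "group_b": b}
            for cov, kind in _BALANCE_COVARIATES:
                row[cov] = standardized_mean_difference(
                    xa[cov].to_numpy(), xb[cov].to_numpy(), binary=(kind == "binary"))
            smd_rows.append(row)
    smd_df = pd.DataFrame(smd_rows)
    return BalanceTable(stats=stats_df, smd=smd_df)


# ---------------------------------------------------------------------------
# placebo poolability

@dataclass
class PoolabilityResult:
    pool: bool
    evidence: pd.DataFrame  # rows: baseline covariates + endpoint measures


def placebo_poolability(subjects: Sequence[SubjectRecord],
                        visits: Sequence["td.VisitRecord"],
                        trials: Mapping[str, td.TrialMeta] | None = None,
                        alpha: float = 0.05) -> PoolabilityResult:
    """Pre-specified check that the two program placebo groups are exchangeable.

    Baseline covariates are compared with two-sample t / chi-square tests;
    endpoint LOCF changes (PANSS total and five factors) with the
    baseline-adjusted ANCOVA contrast.  Pooling is allowed iff every
    endpoint-change p-value exceeds ``alpha``.
    """
    from .efficacy import locf_endpoints, ancova_contrast, EFFICACY_MEASURES

    trials = td.DEFAULT_TRIALS if trials is None else trials
    plc_a = [s for s in subjects if s.treatment_group == PLACEBO_PALI]
    plc_b = [s for s in subjects if s.treatment_group == PLACEBO_RIS]
    if not plc_a or not plc_b:
        raise MatchingError("placebo poolability requires both placebo groups")

    X = _covariate_matrix(plc_a + plc_b)
    ids_a = [s.subject_id for s in plc_a]
    ids_b = [s.subject_id for s in plc_b]
    rows = []
    for cov, kind in _BALANCE_COVARIATES:
        xa, xb = X.loc[ids_a, cov], X.loc[ids_b, cov]
        if kind == "binary":
            tab = np.array([[xa.sum(), len(xa) - xa.sum()],
                            [xb.sum(), len(xb) - xb.sum()]])
            if (tab.sum(axis=0) > 0).all():
                _, p, _, _ = stats.chi2_contingency(tab, correction=False)
            else:
                p = 1.0
        else:
            _, p = stats.ttest_ind(xa, xb)
        rows.append({"item": cov, "kind": "baseline",
                     "placebo_pali": float(xa.mean()),
                     "placebo_ris": float(xb.mean()), "p_value": float(p)})

    endpoint_week = {s.subject_id: trials[s.trial_id].endpoint_week
                     for s in plc_a + plc_b}
    endpoints, _ = locf_endpoints(visits, endpoint_week)
    group_of = {i: PLACEBO_PALI for i in ids_a}
    group_of.update({i: PLACEBO_RIS for i in ids_b})

    endpoint_measures = ["panss_total"] + [f"panss_{f}" for f in td.PANSS_FACTORS]
    all_p_ok = True
    for measure in endpoint_measures:
        sub = endpoints[endpoints["measure"] == measure]
        sub = sub[sub["subject_id"].isin(group_of)]
        if sub.empty:
            continue
        df = sub.assign(group=sub["subject_id"].map(group_of))
        contrast = ancova_contrast(df[["group", "baseline", "change"]])
        c = contrast.contrasts.iloc[0]
        rows.append({"item": measure, "kind": "endpoint_change",
                     "placebo_pali": float(contrast.adjusted_means[PLACEBO_PALI]),
                     "placebo_ris": float(contrast.adjusted_means[PLACEBO_RIS]),
                     "p_value": float(c["p_value"])})
        if c["p_value"] <= alpha:
            all_p_ok = False

    return PoolabilityResult(pool=all_p_ok, evidence=pd.DataFrame(rows))
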