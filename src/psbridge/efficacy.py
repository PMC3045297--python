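"""LOCF endpoint construction and baseline-adjusted group contrasts.

Changes from baseline to the trial-specific endpoint week (4, 6 or 8) use
the last-observation-carried-forward convention: the last post-baseline
value observed at or before the endpoint week is imputed to the endpoint.
Between-group comparisons come from analysis-of-covariance with treatment
as the between-group factor and the baseline value as the covariate
(homogeneous slopes); adjusted means are least-squares means at the grand
baseline mean, pairwise differences carry model-based standard errors and
two-sided t-distribution p-values, and no multiplicity adjustment is made.
Responders show a >=30% decrease in PANSS total from baseline; categorical
rates are compared with Pearson's chi-square without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import trial_data as td
from ._util import round1
from .trial_data import VisitRecord, PANSS_FACTORS


class EfficacyError(ValueError):
    """An endpoint or contrast cannot be computed as requested."""


EFFICACY_MEASURES = (
    ["panss_total"] + [f"panss_{f}" for f in PANSS_FACTORS] + ["cgi_s", "weight_kg"]
)


# ---------------------------------------------------------------------------
# LOCF endpoints

def locf_endpoints(visits: Sequence[VisitRecord],
                   endpoint_week: Mapping[str, int],
                   measures: Sequence[str] = EFFICACY_MEASURES,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Last-observation-carried-forward endpoint per subject and measure.

    Returns a tidy frame (subject_id, measure, baseline, endpoint, change,
    carried_from_week) and the list of subjects excluded for having no
    post-baseline value on any measure.  Exclusion is logged, not raised.
    """
    vf = td.visits_frame(visits)
    vf = vf[vf["subject_id"].isin(endpoint_week)]
    rows = []
    excluded: list[str] = []
    for sid, sub in vf.groupby("subject_id", sort=True):
        w_end = endpoint_week[sid]
        sub = sub.sort_values("week")
        base = sub[sub["week"] == 0]
        post = sub[(sub["week"] >= 1) & (sub["week"] <= w_end)]
        if base.empty:
            excluded.append(sid)
            continue
        any_measure = False
        for measure in measures:
            b = base[measure].iloc[0]
            obs = post[post[measure].notna()]
            if pd.isna(b) or obs.empty:
                continue
            any_measure = True
            last = obs.iloc[-1]
            rows.append({
                "subject_id": sid, "measure": measure,
                "baseline": float(b), "endpoint": float(last[measure]),
                "change": float(last[measure]) - float(b),
                "carried_from_week": int(last["week"]),
            })
        if not any_measure:
            excluded.append(sid)
    cols = ["subject_id", "measure", "baseline", "endpoint", "change",
            "carried_from_week"]
    return pd.DataFrame(rows, columns=cols), excluded


# ---------------------------------------------------------------------------
# responder derivation

def responder_flags(endpoints: pd.DataFrame,
                    groups: Optional[Mapping[str, Sequence[str]]] = None,
                    threshold: float = 0.30,
                    ) -> tuple[pd.Series, Optional[pd.DataFrame]]:
    """Responder = decrease of at least ``threshold`` of baseline PANSS total.

    The inequality is evaluated exactly on the integer scores
    (100*(baseline-endpoint) >= 30*baseline for the default threshold), so
    a decrease of exactly 30% counts as response.  Percentages use the LOCF
    analysis set as denominator.
    """
    panss = endpoints[endpoints["measure"] == "panss_total"]
    if (panss["baseline"] <= 0).any():
        bad = panss.loc[panss["baseline"] <= 0, "subject_id"].iloc[0]
        raise td.ValidationError(
            f"subject {bad!r}: field 'baseline' non-positive PANSS total")
    decrease = panss["baseline"] - panss["endpoint"]
    # integer-exact comparison: decrease/baseline >= threshold
    flags = pd.Series(
        (decrease * 1000 >= threshold * 1000 * panss["baseline"]).to_numpy(),
        index=panss["subject_id"].to_numpy(), name="responder")
    if groups is None:
        return flags, None
    rows = []
    for g, ids in groups.items():
        present = flags.index.intersection(list(ids))
        n = len(present)
        resp = int(flags.loc[present].sum()) if n else 0
        rows.append({"group": g, "n": n, "responders": resp,
                     "pct": round1(100.0 * resp / n) if n else float("nan")})
    return flags, pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# ANCOVA contrast

@dataclass
class ContrastResult:
    measure: Optional[str]
    groups: list[str]
    adjusted_means: pd.Series
    adjusted_se: pd.Series
    contrasts: pd.DataFrame  # group_a, group_b, difference, se, t, p_value
    df_resid: int
    baseline_slope: float
    baseline_dropped: bool


def ancova_contrast(data: pd.DataFrame, measure: Optional[str] = None,
                    ) -> ContrastResult:
    """Least-squares fit of change ~ group + baseline.

    ``data`` needs columns group, baseline, change (one row per subject).
    Adjusted means are evaluated at the grand baseline mean; pairwise
    differences are reported for every group pair with two-sided t tests.
    A zero-variance baseline is dropped from the model with a warning so
    the contrast reduces to a one-way ANOVA on changes.
    """
    req = {"group", "baseline", "change"}
    if not req.issubset(data.columns):
        raise EfficacyError(f"data must have columns {sorted(req)}")
    df = data.dropna(subset=["group", "baseline", "change"]).copy()
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise EfficacyError("at least 2 groups are required")
    counts = df["group"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index[0]
        raise EfficacyError(f"group {small!r} has fewer than 2 subjects")

    y = df["change"].to_numpy(dtype=float)
    baseline = df["baseline"].to_numpy(dtype=float)
    baseline_dropped = bool(np.ptp(baseline) == 0.0)
    if baseline_dropped:
        warnings.warn("baseline covariate has zero variance; dropped from ANCOVA",
                      stacklevel=2)

    k = len(groups)
    n = len(df)
    gidx = pd.Categorical(df["group"], categories=groups).codes
    # design: intercept, k-1 treatment dummies (first group = reference), baseline
    ncol = k + (0 if baseline_dropped else 1)
    X = np.zeros((n, ncol))
    X[:, 0] = 1.0
    for j in range(1, k):
        X[:, j] = (gidx == j)
    if not baseline_dropped:
        X[:, k] = baseline - baseline.mean()  # centered: adjusted means at grand mean

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EfficacyError(
            "singular design: group indicators and baseline are collinear")

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise EfficacyError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df_resid
    cov = sigma2 * np.linalg.inv(XtX)

    def lvec(j: int) -> np.ndarray:
        L = np.zeros(ncol)
        L[0] = 1.0
        if j > 0:
            L[j] = 1.0
        # baseline column is centered, so its contribution at the grand mean is 0
        return L

    adj_mean = pd.Series({g: float(lvec(j) @ beta) for j, g in enumerate(groups)})
    adj_se = pd.Series({g: float(np.sqrt(lvec(j) @ cov @ lvec(j)))
                        for j, g in enumerate(groups)})

    rows = []
    for i, a in enumerate(groups):
        for j, b in enumerate(groups):
            if i >= j:
                continue
            L = lvec(i) - lvec(j)
            diff = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = diff / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), df_resid) if se > 0 else 1.0
            rows.append({"group_a": a, "group_b": b, "difference": diff,
                         "se": se, "t": t, "p_value": p})
    contrasts = pd.DataFrame(rows, columns=["group_a", "group_b", "difference",
                                            "se", "t", "p_value"])
    slope = 0.0 if baseline_dropped else float(beta[k])
    return ContrastResult(measure=measure, groups=groups,
                          adjusted_means=adj_mean, adjusted_se=adj_se,
                          contrasts=contrasts, df_resid=df_resid,
                          baseline_slope=slope, baseline_dropped=baseline_dropped)


# ---------------------------------------------------------------------------
# categorical contrast

def categorical_contrast(table: np.ndarray | Sequence[Sequence[int]],
                         ) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, df, p, expected counts)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or (tab < 0).any() or not np.allclose(tab, np.rint(tab)):
        raise EfficacyError("table must be non-negative integer counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise EfficacyError("table has a zero row or column margin")
    stat, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    return float(stat), int(dof), float(p), expected
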