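"""End-to-end orchestration: simulate/load -> filter -> match -> efficacy -> safety.

A single :class:`RunConfig` drives the full indirect comparison.  Placebo
pooling is applied to the efficacy contrasts only when the pre-specified
poolability check passes; adverse-event comparisons always use the
program-specific placebo groups.  Placebo-adjusted completion rates are
computed on the one-decimal percentage scale (rounded active minus rounded
corresponding placebo).  All stages are deterministic under a fixed seed
and every exclusion, match and endpoint drop is logged as JSON lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import efficacy as eff
from . import propensity_matching as pm
from . import safety as sf
from . import synthetic_trials as st
from . import trial_data as td
from ._util import round1
from .fixtures import FIXTURE_GROUPS, load_ae_incidence, load_summary_rates
from .trial_data import (
    ConfigError, PALI_6_12, RIS_2_4, RIS_4_6, PLACEBO_PALI, PLACEBO_RIS,
)

POOLED_PLACEBO = "POOLED_PLACEBO"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    input_dir: Optional[str] = None     # read subjects/visits/events.csv here...
    suite: Optional[st.ScenarioSuite] = None  # ...or simulate this suite
    seed: int = 0
    caliper: float = pm.DEFAULT_CALIPER
    max_ratio: Optional[int] = None
    responder_threshold: float = 0.30
    ae_incidence_threshold: float = sf.DEFAULT_INCIDENCE_THRESHOLD
    ae_differential_threshold: float = sf.DEFAULT_DIFFERENTIAL_THRESHOLD
    filters: Optional[dict] = None
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.caliper <= 0:
            raise ConfigError("caliper must be positive")
        for name in ("responder_threshold", "ae_incidence_threshold",
                     "ae_differential_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.input_dir is None and self.suite is None:
            self.suite = st.default_suite(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("suite") == "default":
            raw["suite"] = None  # resolved in validate() with the run seed
        return cls(**raw)

    def digest(self) -> str:
        payload = {f.name: repr(getattr(self, f.name))
                   for f in dataclasses.fields(self) if f.name != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    disposition: pd.DataFrame
    balance: pm.BalanceTable
    poolability: pm.PoolabilityResult
    efficacy_table: pd.DataFrame
    response_table: pd.DataFrame
    response_tests: pd.DataFrame
    safety_table: pd.DataFrame
    weight_table: pd.DataFrame
    matched: pm.MatchedPopulation
    provenance: dict
    log: list[dict] = field(default_factory=list)


_EFFICACY_MEASURES = ["panss_total"] + [f"panss_{f}" for f in td.PANSS_FACTORS] + ["cgi_s"]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _pairwise_contrasts(endpoints: pd.DataFrame, measure: str,
                        groups: Mapping[str, Sequence[str]],
                        pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """One two-group ANCOVA per requested pair (overlapping risperidone dose
    groups never contribute duplicate rows to a single model)."""
    sub = endpoints[endpoints["measure"] == measure]
    rows = []
    for a, b in pairs:
        ids_a, ids_b = set(groups[a]), set(groups[b])
        overlap = ids_a & ids_b
        ids_a, ids_b = ids_a - overlap, ids_b - overlap
        group_of = {i: a for i in ids_a}
        group_of.update({i: b for i in ids_b})
        part = sub[sub["subject_id"].isin(group_of)]
        df = part.assign(group=part["subject_id"].map(group_of))
        res = eff.ancova_contrast(df[["group", "baseline", "change"]], measure=measure)
        c = res.contrasts.iloc[0]
        sign = 1.0 if c["group_a"] == a else -1.0
        rows.append({
            "measure": measure, "group_a": a, "group_b": b,
            "adjusted_mean_a": float(res.adjusted_means[a]),
            "se_a": float(res.adjusted_se[a]),
            "adjusted_mean_b": float(res.adjusted_means[b]),
            "se_b": float(res.adjusted_se[b]),
            "difference": sign * float(c["difference"]),
            "se": float(c["se"]), "p_value": float(c["p_value"]),
        })
    return pd.DataFrame(rows)


def adjusted_completion_rates(disposition: pd.DataFrame) -> pd.DataFrame:
    """Placebo-adjusted completion: rounded active % minus rounded program
    placebo %."""
    pct = disposition.set_index("group")["completion_pct"]
    rows = []
    for g, plc in ((PALI_6_12, PLACEBO_PALI), (RIS_2_4, PLACEBO_RIS),
                   (RIS_4_6, PLACEBO_RIS)):
        rows.append({"group": g, "placebo_group": plc,
                     "adjusted_completion_pct": round1(pct[g] - pct[plc])})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and assemble the report tables."""
    config.validate()
    log: list[dict] = []

    @_stage("acquire")
    def acquire():
        if config.input_dir is not None:
            d = Path(config.input_dir)
            subjects = td.read_subject_table(d / "subjects.csv",
                                             require_inclusion=False)
            visits = td.read_visit_table(d / "visits.csv")
            events = td.read_event_table(d / "events.csv")
        else:
            subjects, visits, events = st.generate_cohort(config.suite, config.seed)
        td.validate_visits(visits, subjects)
        td.validate_events(events, visits)
        return subjects, visits, events

    subjects, visits, events = acquire()
    log.append({"stage": "acquire", "n_subjects": len(subjects),
                "n_visits": len(visits), "n_events": len(events)})

    @_stage("filter")
    def filt():
        return td.apply_inclusion_filters(subjects, config.filters)

    retained, exclusion_log = filt()
    log.append({"stage": "filter", "n_retained": len(retained),
                "n_excluded": len(exclusion_log),
                "rules": exclusion_log["rule"].value_counts().to_dict()})

    @_stage("match")
    def match():
        return pm.build_matched_population(retained, caliper=config.caliper,
                                           max_ratio=config.max_ratio)

    matched = match()
    log.append({"stage": "match", "group_sizes": matched.group_sizes()})

    by_id = {s.subject_id: s for s in retained}
    matched_ids = sorted({i for ids in matched.groups.values() for i in ids})
    matched_subjects = [by_id[i] for i in matched_ids]
    matched_visits = [v for v in visits if v.subject_id in set(matched_ids)]
    matched_events = [e for e in events if e.subject_id in set(matched_ids)]

    @_stage("poolability")
    def pool():
        return pm.placebo_poolability(matched_subjects, matched_visits)

    poolability = pool()
    matched.pooled_placebo = poolability.pool
    log.append({"stage": "poolability", "pool": bool(poolability.pool)})

    balance = pm.balance_table(matched_subjects, matched.groups)

    @_stage("efficacy")
    def efficacy_stage():
        endpoint_week = {s.subject_id: td.DEFAULT_TRIALS[s.trial_id].endpoint_week
                         for s in matched_subjects}
        endpoints, dropped = eff.locf_endpoints(matched_visits, endpoint_week)
        groups: dict[str, list[str]] = {g: list(ids)
                                        for g, ids in matched.groups.items()}
        if poolability.pool:
            groups[POOLED_PLACEBO] = sorted(set(groups[PLACEBO_PALI])
                                            | set(groups[PLACEBO_RIS]))
            plc = POOLED_PLACEBO
        else:
            plc = PLACEBO_PALI  # contrasts fall back to program placebos
        pairs = [(PALI_6_12, RIS_2_4), (PALI_6_12, RIS_4_6)]
        if poolability.pool:
            pairs += [(PALI_6_12, plc), (RIS_2_4, plc), (RIS_4_6, plc)]
        else:
            pairs += [(PALI_6_12, PLACEBO_PALI), (RIS_2_4, PLACEBO_RIS),
                      (RIS_4_6, PLACEBO_RIS)]
        tables = [
            _pairwise_contrasts(endpoints, m, groups, pairs)
            for m in _EFFICACY_MEASURES
        ]
        flags, resp_table = eff.responder_flags(
            endpoints, groups, threshold=config.responder_threshold)
        test_rows = []
        for a, b in pairs:
            ids_a = set(groups[a]) - set(groups[b])
            ids_b = set(groups[b]) - set(groups[a])
            fa = flags.loc[flags.index.intersection(ids_a)]
            fb = flags.loc[flags.index.intersection(ids_b)]
            tab = [[int(fa.sum()), int(len(fa) - fa.sum())],
                   [int(fb.sum()), int(len(fb) - fb.sum())]]
            stat, dof, p, _ = eff.categorical_contrast(tab)
            test_rows.append({"group_a": a, "group_b": b,
                              "chi_square": stat, "df": dof, "p_value": p})
        return (pd.concat(tables, ignore_index=True), resp_table,
                pd.DataFrame(test_rows), endpoints, dropped, groups)

    efficacy_table, response_table, response_tests, endpoints, locf_dropped, \
        eff_groups = efficacy_stage()
    log.append({"stage": "efficacy", "n_locf_dropped": len(locf_dropped)})

    @_stage("safety")
    def safety_stage():
        ae_groups = {g: matched.groups[g] for g in
                     (PALI_6_12, PLACEBO_PALI, RIS_2_4, RIS_4_6, PLACEBO_RIS)}
        incidence = sf.incidence_table(matched_events, ae_groups)
        flagged = sf.flag_ae_table(
            incidence, PALI_6_12, PLACEBO_PALI,
            {"vs_RIS_2_4": (RIS_2_4, PLACEBO_RIS),
             "vs_RIS_4_6": (RIS_4_6, PLACEBO_RIS)},
            incidence_threshold=config.ae_incidence_threshold,
            differential_threshold=config.ae_differential_threshold)
        weight_pairs = [(PALI_6_12, RIS_2_4), (PALI_6_12, RIS_4_6),
                        (PALI_6_12, PLACEBO_PALI), (RIS_2_4, PLACEBO_RIS),
                        (RIS_4_6, PLACEBO_RIS)]
        weight = _pairwise_contrasts(endpoints, "weight_kg",
                                     matched.groups, weight_pairs)
        return flagged.table, weight

    safety_table, weight_table = safety_stage()
    log.append({"stage": "safety", "n_flagged_terms": len(safety_table)})

    @_stage("disposition")
    def disposition_stage():
        rows = []
        for g, ids in matched.groups.items():
            recs = [by_id[i] for i in ids]
            n = len(recs)
            nc = sum(r.completed for r in recs)
            rows.append({"group": g, "randomized": n, "completed": nc,
                         "discontinued": n - nc,
                         "completion_pct": round1(100.0 * nc / n)})
        disp = pd.DataFrame(rows)
        return disp.merge(adjusted_completion_rates(disp), on="group", how="left")

    disposition = disposition_stage()

    provenance = {"config_digest": config.digest(), "seed": config.seed,
                  "caliper": config.caliper,
                  "matched_group_sizes": matched.group_sizes(),
                  "pooled_placebo": bool(poolability.pool)}
    report = RunReport(
        disposition=disposition, balance=balance, poolability=poolability,
        efficacy_table=efficacy_table, response_table=response_table,
        response_tests=response_tests, safety_table=safety_table,
        weight_table=weight_table, matched=matched,
        provenance=provenance, log=log)

    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


def _write_report(report: RunReport, out: Path) -> None:
    try:
        out.mkdir(parents=True, exist_ok=True)
        report.disposition.to_csv(out / "disposition.csv", index=False)
        report.balance.stats.to_csv(out / "balance_stats.csv")
        report.balance.smd.to_csv(out / "balance_smd.csv", index=False)
        report.poolability.evidence.to_csv(out / "poolability.csv", index=False)
        report.efficacy_table.to_csv(out / "efficacy.csv", index=False)
        report.response_table.to_csv(out / "response.csv")
        report.response_tests.to_csv(out / "response_tests.csv", index=False)
        report.safety_table.to_csv(out / "safety.csv", index=False)
        report.weight_table.to_csv(out / "weight.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(report.provenance, indent=2, sort_keys=True) + "\n")
        with (out / "log.jsonl").open("w") as fh:
            for entry in report.log:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
    except Exception:
        shutil.rmtree(out, ignore_errors=True)  # no partial outputs
        raise


# ---------------------------------------------------------------------------
# published-number reproduction

def reproduce_fixtures() -> pd.DataFrame:
    """Recompute every derivable published summary cell from published inputs.

    Covers all placebo-adjusted AE differential cells (values and NAs), the
    three placebo-adjusted completion rates, and the active-vs-active
    response-rate differences.  Returns a ledger with one row per cell; the
    run passes iff every row matches exactly.
    """
    rows = []

    ae = load_ae_incidence()
    for _, rec in ae.iterrows():
        for side_label, act_col, printed_col in (
                ("vs_RIS_2_4", "ris_2_4", "printed_diff_vs_2_4"),
                ("vs_RIS_4_6", "ris_4_6", "printed_diff_vs_4_6")):
            d = sf.placebo_adjusted_differential(
                rec[f"{act_col}_pct"], rec["placebo_ris_pct"],
                rec["pali_pct"], rec["placebo_pali_pct"])
            computed = d.magnitude if d.flagged else np.nan
            expected = rec[printed_col]
            ok = (pd.isna(expected) and pd.isna(computed)) or \
                (not pd.isna(expected) and not pd.isna(computed)
                 and float(expected) == float(computed))
            rows.append({"cell": f"{rec['preferred_term']} {side_label}",
                         "expected": expected, "computed": computed,
                         "match": bool(ok)})

    rates = load_summary_rates()
    comp = rates["completion_pct"]
    for g, plc in ((PALI_6_12, PLACEBO_PALI), (RIS_2_4, PLACEBO_RIS),
                   (RIS_4_6, PLACEBO_RIS)):
        computed = round1(round1(comp[g]) - round1(comp[plc]))
        expected = rates["printed_adjusted_completion_pct"][g]
        rows.append({"cell": f"adjusted completion {g}",
                     "expected": expected, "computed": computed,
                     "match": float(expected) == float(computed)})

    resp = rates["response_pct"]
    for key, (a, b) in (("PALI_6_12_vs_RIS_2_4", (PALI_6_12, RIS_2_4)),
                        ("PALI_6_12_vs_RIS_4_6", (PALI_6_12, RIS_4_6))):
        computed = round1(round1(resp[a]) - round1(resp[b]))
        expected = rates["printed_response_diff_pct"][key]
        rows.append({"cell": f"response difference {key}",
                     "expected": expected, "computed": computed,
                     "match": float(expected) == float(computed)})

    return pd.DataFrame(rows, columns=["cell", "expected", "computed", "match"])
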